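"""Evaluation procedures for scored interaction networks.

ROC curves against labelled reference pairs, recovery fractions of pair
sets at an LR cutoff, compartment-crossed negative-set construction,
shared-annotation fractions, LR-binned positive-probability curves, and
multi-subunit complex recovery (bottleneck connectivity threshold, random
null, seeded member prediction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import (Dict, Iterable, List, Mapping, Optional, Sequence, Set,
                    Tuple)

import numpy as np
from scipy.stats import rankdata

from .core import (DEFAULT_RELIABLE_LR, InputError, PairKey, Protein,
                   ReferenceSets)

UNSCORED_LR = 1.0  # pairs with no evidence behave as neutral predictions


@dataclass
class RocCurve:
    """Threshold-indexed (TPR, FPR) points plus the rank-statistic AUC."""

    points: List[Tuple[float, float, float]]  # (threshold, tpr, fpr)
    auc: float


@dataclass(frozen=True)
class ComplexDefinition:
    id: str
    members: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if len(self.members) < 2:
            raise InputError(f"complex {self.id!r} needs >= 2 members")


def roc_curve(scores: Mapping[PairKey, float], refs: ReferenceSets) -> RocCurve:
    """TPR/FPR over all distinct thresholds; unscored pairs count as LR=1.

    TPR(t) = |positives with LR > t| / n_pos, FPR(t) likewise over the
    negatives.  The AUC is the probability that a random positive outscores
    a random negative, ties counting one half.
    """
    if refs.role != "evaluate":
        raise InputError("roc_curve requires reference sets with role='evaluate'")
    if not refs.positives or not refs.negatives:
        raise InputError("both positive and negative pairs are required")
    pos = np.array([scores.get(p, UNSCORED_LR) for p in refs.positives])
    neg = np.array([scores.get(p, UNSCORED_LR) for p in refs.negatives])

    all_scores = np.concatenate([pos, neg])
    ranks = rankdata(all_scores)  # average ranks handle ties at one half
    n_pos, n_neg = len(pos), len(neg)
    auc = (ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    thresholds = np.unique(all_scores)[::-1]
    points: List[Tuple[float, float, float]] = [(float("inf"), 0.0, 0.0)]
    for t in thresholds:
        tpr = float((pos > t).sum()) / n_pos
        fpr = float((neg > t).sum()) / n_neg
        points.append((float(t), tpr, fpr))
    points.append((float("-inf"), 1.0, 1.0))
    return RocCurve(points=points, auc=float(auc))


def recovery_fraction(
    pair_set: Iterable[PairKey],
    scores: Mapping[PairKey, float],
    threshold: float = DEFAULT_RELIABLE_LR,
) -> float:
    """Fraction of a pair set scored strictly above ``threshold``."""
    pair_set = set(pair_set)
    if not pair_set:
        raise InputError("recovery_fraction requires a non-empty pair set")
    hits = sum(1 for p in pair_set if scores.get(p, UNSCORED_LR) > threshold)
    return hits / len(pair_set)


def build_compartment_negatives(
    proteins: Sequence[Protein],
    quota: Mapping[str, int],
    pairing_rules: Sequence[Tuple[str, str]],
    exclusions: Iterable[str] = (),
    seed: int = 0,
) -> Set[PairKey]:
    """Negative pairs from cross-compartment sampling.

    Proteins annotated to more than one of the quota'd compartments, or
    listed in ``exclusions``, never enter any pair.  Sampling is seeded and
    deterministic; each rule contributes the full cross product of the two
    sampled groups.
    """
    exclusions = set(exclusions)
    listed = set(quota)
    eligible: Dict[str, List[str]] = {c: [] for c in listed}
    for prot in proteins:
        if prot.id in exclusions:
            continue
        mine = prot.compartments & listed
        if len(mine) != 1:
            continue  # unannotated or multi-compartment proteins are excluded
        eligible[next(iter(mine))].append(prot.id)

    rng = np.random.default_rng(seed)
    sampled: Dict[str, List[str]] = {}
    for comp, want in quota.items():
        pool = sorted(eligible[comp])
        if len(pool) < want:
            raise InputError(
                f"compartment {comp!r}: quota {want} exceeds {len(pool)} eligible proteins")
        if want == 0:
            sampled[comp] = []
            continue
        idx = rng.choice(len(pool), size=want, replace=False)
        sampled[comp] = [pool[i] for i in sorted(idx)]

    pairs: Set[PairKey] = set()
    for c1, c2 in pairing_rules:
        if c1 not in sampled or c2 not in sampled:
            raise InputError(f"pairing rule references unknown compartment ({c1}, {c2})")
        for x in sampled[c1]:
            for y in sampled[c2]:
                if x != y:
                    pairs.add(PairKey(x, y))
    return pairs


@dataclass
class SharedLabelResult:
    fraction: float
    per_label: Dict[str, float]


def shared_label_fraction(
    pairs: Iterable[PairKey],
    labels: Mapping[str, Set[str]],
) -> SharedLabelResult:
    """Fraction of pairs whose proteins share >= 1 label, with per-label breakdown."""
    pairs = list(pairs)
    if not pairs:
        raise InputError("shared_label_fraction requires a non-empty pair set")
    shared = 0
    per_label_counts: Dict[str, int] = {}
    for pair in pairs:
        common = labels.get(pair.a, set()) & labels.get(pair.b, set())
        if common:
            shared += 1
            for lab in common:
                per_label_counts[lab] = per_label_counts.get(lab, 0) + 1
    n = len(pairs)
    return SharedLabelResult(
        fraction=shared / n,
        per_label={lab: c / n for lab, c in sorted(per_label_counts.items())},
    )


def probability_true_vs_lr(
    scores: Mapping[PairKey, float],
    positives: Set[PairKey],
    lr_bins: Sequence[Tuple[float, float]],
) -> Dict[Tuple[float, float], float]:
    """Per LR bin, fraction of scored pairs that belong to the positive set.

    Bins are closed intervals [lo, hi]; empty bins are omitted from the
    result rather than reported as 0.
    """
    out: Dict[Tuple[float, float], float] = {}
    for lo, hi in lr_bins:
        in_bin = [pair for pair, lr in scores.items() if lo <= lr <= hi]
        if not in_bin:
            continue
        out[(lo, hi)] = sum(1 for p in in_bin if p in positives) / len(in_bin)
    return out


# ---------------------------------------------------------------------------
# Complex recovery
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}
        self.n_components = len(self.parent)

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: str, y: str) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[rx] = ry
            self.n_components -= 1


def complex_recovery_lr(
    complex_def: ComplexDefinition,
    scores: Mapping[PairKey, float],
) -> float:
    """Largest threshold at which the member-induced graph stays connected.

    Equals the bottleneck (minimum edge) of a maximum spanning tree over the
    members, with missing edges weighted 0; a complex that never connects
    through positive-weight edges scores 0.
    """
    members = sorted(complex_def.members)
    edges = []
    for i, u in enumerate(members):
        for v in members[i + 1:]:
            edges.append((scores.get(PairKey(u, v), 0.0), u, v))
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))
    uf = _UnionFind(members)
    for w, u, v in edges:
        uf.union(u, v)
        if uf.n_components == 1:
            return float(w)
    return 0.0


def recovery_curve(
    complexes: Sequence[ComplexDefinition],
    scores: Mapping[PairKey, float],
    thresholds: Optional[Sequence[float]] = None,
) -> List[Tuple[float, float]]:
    """(threshold, fraction of complexes with recovery LR >= threshold)."""
    if not complexes:
        raise InputError("recovery_curve requires at least one complex")
    recov = [complex_recovery_lr(c, scores) for c in complexes]
    if thresholds is None:
        thresholds = sorted(set(recov) | {DEFAULT_RELIABLE_LR})
    return [
        (float(t), sum(1 for r in recov if r >= t) / len(recov))
        for t in thresholds
    ]


def random_complex_null(
    complexes: Sequence[ComplexDefinition],
    protein_universe: Sequence[str],
    scores: Mapping[PairKey, float],
    seed: int = 0,
    thresholds: Optional[Sequence[float]] = None,
) -> List[Tuple[float, float]]:
    """Recovery curve after replacing every complex with a size-matched random one."""
    universe = sorted(set(protein_universe))
    largest = max(len(c.members) for c in complexes)
    if len(universe) <= largest:
        raise InputError("protein universe must exceed the largest complex")
    rng = np.random.default_rng(seed)
    null_complexes = []
    for i, c in enumerate(complexes):
        idx = rng.choice(len(universe), size=len(c.members), replace=False)
        null_complexes.append(ComplexDefinition(
            id=f"null_{c.id}", members=frozenset(universe[j] for j in idx)))
    if thresholds is None:
        real = [complex_recovery_lr(c, scores) for c in complexes]
        null = [complex_recovery_lr(c, scores) for c in null_complexes]
        thresholds = sorted(set(real) | set(null) | {DEFAULT_RELIABLE_LR})
    return recovery_curve(null_complexes, scores, thresholds)


@dataclass
class SeedPredictionResult:
    found_all: bool
    rank_of_last_member: Optional[int]  # None when not all members were found
    within_k: bool
    candidates: List[str] = field(default_factory=list)


def seeded_member_prediction(
    complex_def: ComplexDefinition,
    seed_pair: Tuple[str, str],
    scores: Mapping[PairKey, float],
    threshold: float = DEFAULT_RELIABLE_LR,
    k: int = 10,
) -> SeedPredictionResult:
    """Recover the remaining members from two seed members' partners.

    Candidates are proteins with LR > threshold to either seed, ranked by
    the larger of their two seed LRs (ties broken lexicographically).
    """
    s1, s2 = seed_pair
    if s1 not in complex_def.members or s2 not in complex_def.members:
        raise InputError("seed proteins must belong to the complex")
    best: Dict[str, float] = {}
    for pair, lr in scores.items():
        for seed in (s1, s2):
            if seed in (pair.a, pair.b):
                other = pair.other(seed)
                if other not in (s1, s2) and lr > threshold:
                    best[other] = max(best.get(other, 0.0), lr)
    candidates = sorted(best, key=lambda p: (-best[p], p))
    targets = complex_def.members - {s1, s2}
    ranks = {p: i + 1 for i, p in enumerate(candidates)}
    found_all = targets <= set(candidates)
    rank_last = max((ranks[t] for t in targets), default=0) if found_all else None
    within_k = bool(found_all and rank_last is not None and rank_last <= k)
    return SeedPredictionResult(found_all=found_all,
                                rank_of_last_member=rank_last,
                                within_k=within_k,
                                candidates=candidates)
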