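"""Function annotation of a query protein by ranked-list gene set enrichment.

All other proteins are ranked by their interaction LR with the query; gene
sets concentrated at the top of that ranking (weighted running-sum statistic,
label-permutation p-values, Benjamini-Hochberg q-values) supply candidate
annotations for the query.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from statsmodels.stats.multitest import multipletests

from .core import InputError, PairKey

DEFAULT_Q_THRESHOLD = 0.01
DEFAULT_N_PERMUTATIONS = 1000


@dataclass
class RankedInteractorList:
    """Interactors of a query, strictly ordered by descending LR then id."""

    query: str
    items: List[Tuple[str, float]]

    @property
    def ids(self) -> List[str]:
        return [pid for pid, _ in self.items]

    @property
    def lrs(self) -> List[float]:
        return [lr for _, lr in self.items]


@dataclass(frozen=True)
class GeneSet:
    name: str
    term: str
    members: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise InputError(f"gene set {self.name!r} is empty")


@dataclass
class EnrichmentResult:
    name: str
    term: str
    es: float
    p: float
    q: float
    rank: int = 0
    enriched: bool = False


def rank_interactors(
    query: str,
    scores: Mapping[PairKey, float],
    universe: Optional[Iterable[str]] = None,
) -> RankedInteractorList:
    """All proteins ranked by LR versus the query; unscored universe members get LR 1."""
    lrs: Dict[str, float] = {}
    for pair, lr in scores.items():
        if query in (pair.a, pair.b):
            lrs[pair.other(query)] = float(lr)
    if universe is not None:
        for pid in universe:
            if pid != query and pid not in lrs:
                lrs[pid] = 1.0
    items = sorted(lrs.items(), key=lambda kv: (-kv[1], kv[0]))
    return RankedInteractorList(query=query, items=items)


def _weights(lrs: Sequence[float], mode: str, exponent: float) -> np.ndarray:
    if mode == "log10":
        w = np.array([math.log10(max(lr, 1.0)) for lr in lrs])
    elif mode == "raw":
        w = np.asarray(lrs, dtype=float)
    elif mode == "rank":
        w = np.ones(len(lrs))
    else:
        raise InputError(f"unknown weight mode {mode!r}")
    return np.abs(w) ** exponent


def _running_sum_es(hit: np.ndarray, weights: np.ndarray) -> float:
    """Signed maximum deviation of the weighted running sum."""
    n = hit.size
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise InputError("gene set has no member in the ranking universe")
    hit_w = np.where(hit, weights, 0.0)
    denom = hit_w.sum()
    if denom > 0:
        inc = hit_w / denom
    else:
        inc = hit.astype(float) / n_hits  # degenerate all-zero weights
    if n > n_hits:
        inc = inc - (~hit).astype(float) / (n - n_hits)
    running = np.cumsum(inc)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def enrichment_score(
    ranked: RankedInteractorList,
    gene_set: GeneSet,
    weight_exponent: float = 1.0,
    weight_mode: str = "log10",
) -> float:
    """Weighted running-sum enrichment of a gene set at the top of the ranking.

    Hits advance the sum by their normalised |weight|^p, misses retreat by
    1/(N - N_hits); the statistic is the signed extremum of the walk.
    """
    hit = np.array([pid in gene_set.members for pid in ranked.ids])
    weights = _weights(ranked.lrs, weight_mode, weight_exponent)
    return _running_sum_es(hit, weights)


def enrichment_analysis(
    ranked: RankedInteractorList,
    sets: Sequence[GeneSet],
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    weight_exponent: float = 1.0,
    weight_mode: str = "log10",
) -> List[EnrichmentResult]:
    """Score every gene set, with permutation p-values and BH q-values.

    The null permutes gene labels across ranking positions (weights stay
    attached to positions); p is one-sided for enrichment at the top.
    Results come back sorted by descending enrichment score.
    """
    if n_permutations < 100:
        raise InputError("n_permutations must be >= 100")
    ids = ranked.ids
    n = len(ids)
    if n == 0:
        raise InputError("empty ranking")
    weights = _weights(ranked.lrs, weight_mode, weight_exponent)
    hit_arrays = []
    observed = []
    for gs in sets:
        hit = np.array([pid in gs.members for pid in ids])
        hit_arrays.append(hit)
        observed.append(_running_sum_es(hit, weights))

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(sets), dtype=np.int64)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        for j, hit in enumerate(hit_arrays):
            null_es = _running_sum_es(hit[perm], weights)
            if null_es >= observed[j]:
                exceed[j] += 1
    pvals = (1.0 + exceed) / (1.0 + n_permutations)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")

    results = [
        EnrichmentResult(name=gs.name, term=gs.term, es=float(es),
                         p=float(p), q=float(q))
        for gs, es, p, q in zip(sets, observed, pvals, qvals)
    ]
    results.sort(key=lambda r: (-r.es, r.name))
    for i, r in enumerate(results):
        r.rank = i + 1
        r.enriched = r.q < q_threshold
    return results


def first_correct_rank(
    results: Sequence[EnrichmentResult],
    true_terms: Set[str],
) -> Optional[int]:
    """1-based position of the first result carrying a known-correct term."""
    for i, r in enumerate(results):
        if r.term in true_terms:
            return i + 1
    return None
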