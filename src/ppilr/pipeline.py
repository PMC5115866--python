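"""End-to-end feature building, model training, and pair scoring.

Ties the evidence channels together: derives per-pair orthology vectors,
partner-redundancy features and expression scores from their raw inputs,
trains one binned LR model per channel on a labelled training split, and
combines per-channel LRs into total scores for every evidence-bearing pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .core import (BinnedLRModel, CombinedScore, InputError, IntervalBins,
                   PairKey, ReferenceSets, combine_evidence, fit_binned_lr)
from .expression import ep_score
from .orthology import (DEFAULT_MIN_SUPPORT, SOURCES, OrthologMap,
                        OrthologyVector, default_backoff_order,
                        fit_orthology_models, pair_vector, score_with_backoff)
from .partner_redundancy import (PartnerRedundancyFeatures,
                                 StructuralNeighborhood, compute_features,
                                 default_m_bins, default_nd_bins, score_pr)

CONTINUOUS_CHANNELS = ("SM", "PrP", "GO", "PP", "EP")


@dataclass
class FeatureTable:
    """Per-pair channel features for a fixed pair universe."""

    pairs: List[PairKey]
    continuous: Dict[str, Dict[PairKey, float]]
    or_vectors: Dict[PairKey, OrthologyVector]
    pr_features: Dict[PairKey, PartnerRedundancyFeatures]


def compute_ep_scores(
    correlations: Mapping[str, Mapping[PairKey, float]],
    dataset_manifest: Mapping[str, Mapping[str, object]],
    pairs: Iterable[PairKey],
) -> Dict[PairKey, float]:
    """Expression-profile score per pair; pairs with no data are omitted."""
    human_ds = [ds for ds, meta in dataset_manifest.items() if meta.get("human")]
    other_ds = [ds for ds in dataset_manifest if ds not in human_ds]
    out: Dict[PairKey, float] = {}
    for pair in pairs:
        human = [correlations[ds][pair] for ds in human_ds
                 if pair in correlations.get(ds, {})]
        orth = [correlations[ds][pair] for ds in other_ds
                if pair in correlations.get(ds, {})]
        score = ep_score(human, orth)
        if score is not None:
            out[pair] = score
    return out


def compute_or_vectors(
    pairs: Iterable[PairKey],
    maps: Mapping[str, OrthologMap],
    species_interactions: Set[Tuple[str, PairKey]],
) -> Dict[PairKey, OrthologyVector]:
    """Orthology vector per pair.

    A pair only carries orthology evidence when at least one source maps
    both proteins to some ortholog; otherwise the channel is absent.
    """
    out: Dict[PairKey, OrthologyVector] = {}
    for pair in pairs:
        has_data = any(
            maps[s].orthologs.get(pair.a) and maps[s].orthologs.get(pair.b)
            for s in SOURCES if s in maps)
        if not has_data:
            continue
        out[pair] = pair_vector(pair, maps, species_interactions)
    return out


def compute_pr_features(
    pairs: Iterable[PairKey],
    nbhd: StructuralNeighborhood,
    known_human: Set[PairKey],
    known_any: Set[PairKey],
) -> Dict[PairKey, PartnerRedundancyFeatures]:
    """Symmetrised partner-redundancy features per pair.

    The ordered features are computed in both directions and the direction
    with the stronger (n, m, d) profile represents the pair, keeping every
    downstream score invariant under protein swap.
    """
    degrees: Dict[str, int] = {}
    for p in known_human:
        degrees[p.a] = degrees.get(p.a, 0) + 1
        degrees[p.b] = degrees.get(p.b, 0) + 1
    out: Dict[PairKey, PartnerRedundancyFeatures] = {}
    for pair in pairs:
        f_ab = compute_features(pair.a, pair.b, nbhd, known_human, known_any,
                                degrees=degrees)
        f_ba = compute_features(pair.b, pair.a, nbhd, known_human, known_any,
                                degrees=degrees)
        out[pair] = max(f_ab, f_ba, key=lambda f: (f.n, f.m, f.d))
    return out


def build_features(
    evidence: Mapping[PairKey, Mapping[str, float]],
    ortholog_maps: Mapping[str, OrthologMap],
    species_interactions: Set[Tuple[str, PairKey]],
    correlations: Mapping[str, Mapping[PairKey, float]],
    dataset_manifest: Mapping[str, Mapping[str, object]],
    neighborhoods: StructuralNeighborhood,
    known_human: Set[PairKey],
    known_any: Set[PairKey],
    pairs: Optional[Sequence[PairKey]] = None,
) -> FeatureTable:
    """Assemble every channel's per-pair features over one pair universe."""
    if pairs is None:
        pairs = list(evidence.keys())
    continuous: Dict[str, Dict[PairKey, float]] = {
        ch: {p: ev[ch] for p, ev in evidence.items() if ch in ev}
        for ch in ("SM", "PrP", "GO", "PP")
    }
    continuous["EP"] = compute_ep_scores(correlations, dataset_manifest, pairs)
    return FeatureTable(
        pairs=list(pairs),
        continuous=continuous,
        or_vectors=compute_or_vectors(pairs, ortholog_maps, species_interactions),
        pr_features=compute_pr_features(pairs, neighborhoods, known_human,
                                        known_any),
    )


@dataclass
class TrainedModels:
    """One binned LR model per channel (plus orthology backoff stack)."""

    continuous: Dict[str, BinnedLRModel]
    orthology: Dict[Tuple[str, ...], BinnedLRModel]
    pr_first: BinnedLRModel
    pr_second: BinnedLRModel
    min_support: int = DEFAULT_MIN_SUPPORT
    square_pr: bool = False

    def to_dict(self) -> dict:
        return {
            "continuous": {ch: m.to_dict() for ch, m in self.continuous.items()},
            "orthology": {"+".join(k): m.to_dict()
                          for k, m in self.orthology.items()},
            "pr_first": self.pr_first.to_dict(),
            "pr_second": self.pr_second.to_dict(),
            "min_support": self.min_support,
            "square_pr": self.square_pr,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedModels":
        return cls(
            continuous={ch: BinnedLRModel.from_dict(m)
                        for ch, m in d["continuous"].items()},
            orthology={tuple(k.split("+")): BinnedLRModel.from_dict(m)
                       for k, m in d["orthology"].items()},
            pr_first=BinnedLRModel.from_dict(d["pr_first"]),
            pr_second=BinnedLRModel.from_dict(d["pr_second"]),
            min_support=int(d["min_support"]),
            square_pr=bool(d["square_pr"]),
        )


def train_models(
    features: FeatureTable,
    refs: ReferenceSets,
    n_bins: int = 10,
    pseudo_count: float = 0.5,
    min_support: int = DEFAULT_MIN_SUPPORT,
    square_pr: bool = False,
) -> TrainedModels:
    """Fit every channel's LR model on the training reference split.

    Continuous channels use equal-frequency quantile bins of the training
    pool; orthology trains one categorical model per source subset; partner
    redundancy trains the (n, d) and m networks.
    """
    if refs.role != "train":
        raise InputError("train_models requires reference sets with role='train'")
    train_pairs = set(refs.positives) | set(refs.negatives)

    continuous: Dict[str, BinnedLRModel] = {}
    for ch in CONTINUOUS_CHANNELS:
        ch_scores = features.continuous.get(ch, {})
        pool = [v for p, v in ch_scores.items() if p in train_pairs]
        if not pool:
            continue  # channel absent from the training data entirely
        bins = IntervalBins.from_quantiles(pool, n_bins)
        continuous[ch] = fit_binned_lr(ch_scores, refs, bins,
                                       pseudo_count=pseudo_count, channel=ch)

    orthology = fit_orthology_models(features.or_vectors, refs,
                                     pseudo_count=pseudo_count)

    nd_scores = {p: f.nd for p, f in features.pr_features.items()}
    m_scores = {p: f.m for p, f in features.pr_features.items()}
    pr_first = fit_binned_lr(nd_scores, refs, default_nd_bins(),
                             pseudo_count=pseudo_count, channel="PR_nd")
    pr_second = fit_binned_lr(m_scores, refs, default_m_bins(),
                              pseudo_count=pseudo_count, channel="PR_m")
    return TrainedModels(continuous=continuous, orthology=orthology,
                         pr_first=pr_first, pr_second=pr_second,
                         min_support=min_support, square_pr=square_pr)


def score_pairs(
    features: FeatureTable,
    models: TrainedModels,
    has_structure: Optional[Mapping[str, bool]] = None,
    exclude_channels: Sequence[str] = (),
) -> Dict[PairKey, CombinedScore]:
    """Combined LR for every pair in the feature table.

    ``exclude_channels`` removes channels from the product (e.g. drop GO
    when validating annotations that derive from GO).  The second partner-
    redundancy network is only consulted when both proteins have a structure
    or model (``has_structure`` defaulting to available).
    """
    exclude = set(exclude_channels)
    backoff = default_backoff_order()
    out: Dict[PairKey, CombinedScore] = {}
    for pair in features.pairs:
        lrs: Dict[str, float] = {}
        for ch, model in models.continuous.items():
            if ch in exclude:
                continue
            ch_scores = features.continuous.get(ch, {})
            if pair in ch_scores:
                lrs[ch] = model.lookup(ch_scores[pair])
        if "OR" not in exclude and pair in features.or_vectors:
            lrs["OR"] = score_with_backoff(
                features.or_vectors[pair], models.orthology,
                min_support=models.min_support, order=backoff)
        if "PR" not in exclude and pair in features.pr_features:
            if has_structure is None:
                b_ok = True
            else:
                b_ok = bool(has_structure.get(pair.a, False)
                            and has_structure.get(pair.b, False))
            lr_pr, _ = score_pr(features.pr_features[pair], models.pr_first,
                                models.pr_second,
                                min_support=models.min_support,
                                b_has_structure=b_ok)
            lrs["PR"] = lr_pr
        out[pair] = combine_evidence(lrs, pair=pair, square_pr=models.square_pr)
    return out


def total_lrs(scores: Mapping[PairKey, CombinedScore]) -> Dict[PairKey, float]:
    """Collapse combined scores to a plain pair -> total-LR mapping."""
    return {p: s.lr_total for p, s in scores.items()}
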