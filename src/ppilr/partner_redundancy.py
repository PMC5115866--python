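"""Partner-redundancy evidence.

If proteins structurally similar to A are already known to interact with B,
A itself is more likely to bind B.  Two binned models capture this: the
first over (n, d) -- neighbours of A interacting with B, and B's known
degree -- restricted to the curated human interaction set; the second over
m, the count of neighbour-neighbour interactions observed in any species.
The first model is preferred when its bin is adequately supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Set, Tuple, Union

from .core import (BinnedLRModel, GridBins, InputError, IntervalBins, PairKey)

INF = float("inf")

#: Default n-axis edges: {0}, {1}, [2,5], [6,inf).
DEFAULT_N_EDGES = (0.0, 1.0, 2.0, 6.0, INF)
#: Default d-axis edges: [0,100], (100,inf).
DEFAULT_D_EDGES = (0.0, 101.0, INF)
#: Default m edges: {0}, {1}, [2,5], [6,20], [21,inf).
DEFAULT_M_EDGES = (0.0, 1.0, 2.0, 6.0, 21.0, INF)

DEFAULT_MIN_SUPPORT = 10


def default_nd_bins() -> GridBins:
    return GridBins([IntervalBins(DEFAULT_N_EDGES), IntervalBins(DEFAULT_D_EDGES)])


def default_m_bins() -> IntervalBins:
    return IntervalBins(DEFAULT_M_EDGES)


@dataclass
class StructuralNeighborhood:
    """protein id -> ids of structurally similar proteins."""

    neighbors: Dict[str, Set[str]] = field(default_factory=dict)

    def of(self, protein: str, exclude: Iterable[str] = ()) -> Set[str]:
        """Neighbour set of ``protein`` with ``exclude`` (and itself) removed."""
        return self.neighbors.get(protein, set()) - {protein, *exclude}


@dataclass(frozen=True)
class PartnerRedundancyFeatures:
    """(n, d, m) counts for one ordered pair, plus which network scored it."""

    n: int
    d: int
    m: int
    which_network: str = "none"  # first | second | none

    def __post_init__(self) -> None:
        if min(self.n, self.d, self.m) < 0:
            raise InputError("partner-redundancy counts must be nonnegative")

    @property
    def nd(self) -> Tuple[int, int]:
        return (self.n, self.d)


def _as_pairs(known: Iterable) -> Set[PairKey]:
    """Accept either PairKey or (species, PairKey) elements; collapse species."""
    if isinstance(known, (set, frozenset)):
        probe = next(iter(known), None)
        if probe is None or isinstance(probe, PairKey):
            return known  # already a plain pair set; no copy needed
    out: Set[PairKey] = set()
    for item in known:
        if isinstance(item, PairKey):
            out.add(item)
        else:
            out.add(item[1])
    return out


def compute_features(
    a: str,
    b: str,
    nbhd: StructuralNeighborhood,
    known_human: Set[PairKey],
    known_any_species: Iterable[Union[PairKey, Tuple[str, PairKey]]],
    degrees: Optional[Dict[str, int]] = None,
) -> PartnerRedundancyFeatures:
    """Count (n, d, m) for the ordered pair (a, b).

    n: neighbours of ``a`` (with a and b excluded) known to interact with
    ``b`` in the curated human set; d: degree of ``b`` in that set; m:
    neighbour-of-a x neighbour-of-b pairs interacting in any species
    (distinct pairs, species collapsed).  ``degrees`` optionally supplies
    precomputed known-human degrees to avoid rescanning the set per call.
    """
    na = nbhd.of(a, exclude=(b,))
    nb = nbhd.of(b, exclude=(a,))
    n = sum(1 for x in na if x != b and PairKey(x, b) in known_human)
    if degrees is not None:
        d = int(degrees.get(b, 0))
    else:
        d = sum(1 for pair in known_human if b in (pair.a, pair.b))
    any_pairs = _as_pairs(known_any_species)
    m = 0
    for x in na:
        for y in nb:
            if x == y:
                continue
            if PairKey(x, y) in any_pairs:
                m += 1
    return PartnerRedundancyFeatures(n=n, d=d, m=m)


def score_pr(
    features: PartnerRedundancyFeatures,
    first_model: BinnedLRModel,
    second_model: Optional[BinnedLRModel],
    min_support: int = DEFAULT_MIN_SUPPORT,
    b_has_structure: bool = True,
) -> Tuple[float, str]:
    """LR with first-network preference and second-network fallback.

    Returns (lr, which_network).  The first (human, (n,d)-binned) network is
    used when its bin has adequate training support; otherwise the second
    (any-species, m-binned) network is used, which requires a structure or
    model for B; otherwise the evidence is neutral.
    """
    try:
        idx = first_model.bins.assign(features.nd)
    except InputError:
        idx = None
    if idx is not None and first_model.pos_counts[idx] + first_model.neg_counts[idx] >= min_support:
        return float(first_model.lr[idx]), "first"
    if second_model is not None and b_has_structure:
        try:
            jdx = second_model.bins.assign(features.m)
        except InputError:
            jdx = None
        if jdx is not None and second_model.pos_counts[jdx] + second_model.neg_counts[jdx] >= min_support:
            return float(second_model.lr[jdx]), "second"
    return 1.0, "none"
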