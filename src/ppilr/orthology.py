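"""Orthology-transfer evidence: four-source interaction vectors with backoff.

For a pair (A, B), each orthology source contributes the number of *species*
in which some ortholog of A interacts with some ortholog of B, truncated to
{0, 1, >1}.  The resulting four-component vector indexes a categorical LR
bin; sparsely observed bins back off to lower-dimensional source subsets in
a fixed priority order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .core import (BinnedLRModel, CategoricalBins, InputError, PairKey,
                   ReferenceSets, fit_binned_lr)

#: The four source groups, in vector-component order.
SOURCES = ("gopher", "oma", "kegg", "union_group")

#: Default minimum (pos + neg) training pairs for a bin to be trusted.
DEFAULT_MIN_SUPPORT = 10


def default_backoff_order(sources: Sequence[str] = SOURCES) -> List[Tuple[str, ...]]:
    """Full-dimension subset first, then all 3-, 2-, 1-source subsets.

    Within a dimension, subsets are enumerated in source order, which makes
    the backoff deterministic and reproducible.
    """
    order: List[Tuple[str, ...]] = []
    for r in range(len(sources), 0, -1):
        order.extend(itertools.combinations(sources, r))
    return order


@dataclass
class OrthologMap:
    """One source's protein -> {(species, ortholog id)} mapping."""

    source: str
    orthologs: Dict[str, Set[Tuple[str, str]]] = field(default_factory=dict)
    _by_species: Dict[str, Dict[str, Set[str]]] = field(
        default_factory=dict, repr=False, compare=False)

    def species_orthologs(self, protein: str) -> Dict[str, Set[str]]:
        """Orthologs of ``protein`` grouped by species (cached)."""
        cached = self._by_species.get(protein)
        if cached is None:
            cached = {}
            for species, oid in self.orthologs.get(protein, ()):
                cached.setdefault(species, set()).add(oid)
            self._by_species[protein] = cached
        return cached


@dataclass(frozen=True)
class OrthologyVector:
    """Per-source truncated species counts; 2 encodes '>1'."""

    components: Tuple[int, ...]
    dimension_used: Tuple[str, ...] = SOURCES

    def __post_init__(self) -> None:
        if any(c not in (0, 1, 2) for c in self.components):
            raise InputError(f"vector components must be 0/1/2: {self.components}")

    def project(self, subset: Sequence[str],
                sources: Sequence[str] = SOURCES) -> Tuple[int, ...]:
        """Components restricted to ``subset`` of the source groups."""
        idx = {s: i for i, s in enumerate(sources)}
        return tuple(self.components[idx[s]] for s in subset)


def count_orthologous_interactions(
    a: str,
    b: str,
    ortholog_map: OrthologMap,
    other_species_interactions: Set[Tuple[str, PairKey]],
) -> int:
    """Number of distinct species with an interacting ortholog pair of (a, b)."""
    by_species_a = ortholog_map.species_orthologs(a)
    by_species_b = ortholog_map.species_orthologs(b)
    count = 0
    for species in by_species_a.keys() & by_species_b.keys():
        found = False
        for oa in by_species_a[species]:
            for ob in by_species_b[species]:
                if oa == ob:
                    continue
                if (species, PairKey(oa, ob)) in other_species_interactions:
                    found = True
                    break
            if found:
                break
        if found:
            count += 1
    return count


def build_vector(counts_per_source: Sequence[int],
                 sources: Sequence[str] = SOURCES) -> OrthologyVector:
    """Truncate per-source species counts to {0, 1, >1} components."""
    if len(counts_per_source) != len(sources):
        raise InputError(
            f"expected {len(sources)} counts, got {len(counts_per_source)}")
    if any(c < 0 for c in counts_per_source):
        raise InputError("counts must be nonnegative")
    return OrthologyVector(
        components=tuple(min(int(c), 2) for c in counts_per_source),
        dimension_used=tuple(sources),
    )


def pair_vector(
    pair: PairKey,
    maps: Mapping[str, OrthologMap],
    other_species_interactions: Set[Tuple[str, PairKey]],
    sources: Sequence[str] = SOURCES,
) -> OrthologyVector:
    """Convenience: count per source then build the vector for one pair."""
    counts = [
        count_orthologous_interactions(pair.a, pair.b, maps[s],
                                       other_species_interactions)
        if s in maps else 0
        for s in sources
    ]
    return build_vector(counts, sources)


def all_vector_bins(dimension: int) -> CategoricalBins:
    """Exhaustive categorical partition over {0,1,2}^dimension."""
    return CategoricalBins(itertools.product((0, 1, 2), repeat=dimension))


def fit_orthology_models(
    vectors: Mapping[PairKey, OrthologyVector],
    refs: ReferenceSets,
    pseudo_count: float = 0.5,
    subsets: Optional[Iterable[Tuple[str, ...]]] = None,
    sources: Sequence[str] = SOURCES,
) -> Dict[Tuple[str, ...], BinnedLRModel]:
    """Train one categorical model per source subset in the backoff order."""
    if subsets is None:
        subsets = default_backoff_order(sources)
    models: Dict[Tuple[str, ...], BinnedLRModel] = {}
    for subset in subsets:
        projected = {pair: v.project(subset, sources) for pair, v in vectors.items()}
        models[subset] = fit_binned_lr(
            projected, refs, all_vector_bins(len(subset)),
            pseudo_count=pseudo_count, channel="OR:" + "+".join(subset))
    return models


def score_with_backoff(
    vector: OrthologyVector,
    models: Mapping[Tuple[str, ...], BinnedLRModel],
    min_support: int = DEFAULT_MIN_SUPPORT,
    order: Optional[Sequence[Tuple[str, ...]]] = None,
    sources: Sequence[str] = SOURCES,
) -> float:
    """LR from the highest-dimensional sufficiently supported bin, else 1.

    Models are consulted in ``order`` (default: full dimension first, then
    ever smaller subsets); the first bin whose training support reaches
    ``min_support`` wins.
    """
    if order is None:
        order = default_backoff_order(sources)
    for subset in order:
        model = models.get(tuple(subset))
        if model is None:
            continue
        try:
            idx = model.bins.assign(vector.project(subset, sources))
        except InputError:
            continue
        if model.pos_counts[idx] + model.neg_counts[idx] >= min_support:
            return float(model.lr[idx])
    return 1.0
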