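"""Seeded generator of complete synthetic input bundles.

A modular ground-truth interaction graph (stochastic block model) drives
every other artefact: channel scores drawn from class-conditional
distributions, ortholog maps with per-source dropout and optional pure-noise
sources, per-dataset expression correlations, structural neighbourhoods and
known-interaction sets, compartment labels, train/evaluate reference splits,
complexes and gene sets derived from the modules, and interface/variant
placements with a planted enrichment odds ratio.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .core import InputError, PairKey, Protein, ReferenceSets
from .evaluation import ComplexDefinition, build_compartment_negatives
from .gsea import GeneSet
from .orthology import SOURCES, OrthologMap
from .partner_redundancy import StructuralNeighborhood

DEFAULT_COMPARTMENTS = ("membrane", "nucleoplasm", "mitochondria", "er")
DEFAULT_COMPARTMENT_PROBS = (0.45, 0.25, 0.2, 0.1)
CONTINUOUS_CHANNELS = ("SM", "PrP", "GO", "PP")


@dataclass
class WorldConfig:
    """All knobs of the generator; a fixed seed fixes the whole bundle."""

    n_proteins: int = 2000
    n_modules: int = 50
    p_within: float = 0.3
    p_background: float = 0.001
    n_negative_sample: int = 30000

    # class-conditional channel emissions: channel -> (mu_pos, mu_neg, sigma)
    channel_params: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: {
            "SM": (1.5, 0.0, 1.0),
            "PrP": (1.0, 0.0, 1.0),
            "GO": (1.2, 0.0, 1.0),
            "PP": (1.0, 0.0, 1.0),
        })
    channel_coverage: Dict[str, float] = field(
        default_factory=lambda: {"SM": 0.7, "PrP": 0.4, "GO": 0.8, "PP": 0.6})

    # orthology
    n_species: int = 10
    source_coverage: Dict[str, float] = field(
        default_factory=lambda: {
            "gopher": 0.8, "oma": 0.7, "kegg": 0.5, "union_group": 0.85})
    noise_sources: Tuple[str, ...] = ()
    p_propagate: float = 0.5
    p_or_noise: float = 0.01

    # expression
    n_human_datasets: int = 3
    corr_coverage: float = 0.6
    corr_mu_pos: float = 0.5
    corr_mu_neg: float = 0.0
    corr_sd: float = 0.25

    # partner redundancy
    n_struct_neighbors: int = 8
    n_noise_neighbors: int = 2
    known_human_fraction: float = 0.4
    known_any_fraction: float = 0.5
    p_has_structure: float = 0.9

    # compartments / negatives
    compartments: Tuple[str, ...] = DEFAULT_COMPARTMENTS
    compartment_probs: Tuple[float, ...] = DEFAULT_COMPARTMENT_PROBS
    p_dual_compartment: float = 0.02
    negative_quota_frac: float = 0.5

    # complexes & gene sets
    complex_size_range: Tuple[int, int] = (3, 8)
    gene_set_dropout: float = 0.1
    n_decoy_sets: int = 50

    # interfaces & variants
    n_residues: int = 50
    interface_fraction: float = 0.2
    variant_rate: float = 0.02
    theta: float = 2.0

    train_fraction: float = 0.5
    null_world: bool = False  # decouple every evidence source from the truth
    seed: int = 0

    def validate(self) -> None:
        probs = [self.p_within, self.p_background, self.p_propagate,
                 self.p_or_noise, self.corr_coverage, self.p_dual_compartment,
                 self.train_fraction, self.known_human_fraction,
                 self.known_any_fraction, self.interface_fraction,
                 self.variant_rate, self.p_has_structure]
        probs += list(self.channel_coverage.values())
        probs += list(self.source_coverage.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise InputError("all probabilities must lie in [0, 1]")
        if self.n_proteins < self.n_modules or self.n_modules < 1:
            raise InputError("need 1 <= n_modules <= n_proteins")
        if abs(sum(self.compartment_probs) - 1.0) > 1e-9:
            raise InputError("compartment probabilities must sum to 1")
        if self.theta <= 0:
            raise InputError("theta must be positive")
        if any(s not in SOURCES for s in self.noise_sources):
            raise InputError(f"noise_sources must be among {SOURCES}")


@dataclass
class SyntheticWorld:
    """In-memory bundle of everything the scoring/evaluation stack consumes."""

    config: WorldConfig
    proteins: Dict[str, Protein]
    modules: List[List[str]]
    true_edges: Set[PairKey]
    scored_pairs: List[PairKey]
    evidence: Dict[PairKey, Dict[str, float]]
    ortholog_maps: Dict[str, OrthologMap]
    species_interactions: Set[Tuple[str, PairKey]]
    correlations: Dict[str, Dict[PairKey, float]]
    dataset_manifest: Dict[str, Dict[str, object]]
    neighborhoods: StructuralNeighborhood
    known_human: Set[PairKey]
    known_any: Set[PairKey]
    refs_train: ReferenceSets
    refs_eval: ReferenceSets
    complexes: List[ComplexDefinition]
    gene_sets: List[GeneSet]
    protein_terms: Dict[str, Set[str]]
    interface_mask: Dict[Tuple[str, int], bool]
    variants: Set[Tuple[str, int]]

    @property
    def species(self) -> List[str]:
        return [f"sp{i:02d}" for i in range(self.config.n_species)]


def _pair(ids: Sequence[str], i: int, j: int) -> PairKey:
    return PairKey(ids[i], ids[j])


def generate(config: Optional[WorldConfig] = None, **overrides) -> SyntheticWorld:
    """Sample a full synthetic world; identical seeds give identical bundles."""
    if config is None:
        config = WorldConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    ids = [f"P{i:05d}" for i in range(n)]

    # --- modules and ground-truth graph ------------------------------------
    order = rng.permutation(n)
    bounds = np.linspace(0, n, config.n_modules + 1).astype(int)
    modules = [[ids[k] for k in sorted(order[bounds[m]:bounds[m + 1]])]
               for m in range(config.n_modules)]
    module_of = np.empty(n, dtype=np.int64)
    for m in range(config.n_modules):
        module_of[order[bounds[m]:bounds[m + 1]]] = m

    iu, ju = np.triu_indices(n, 1)
    same = module_of[iu] == module_of[ju]
    p_edge = np.where(same, config.p_within, config.p_background)
    edge_mask = rng.random(iu.size) < p_edge
    edge_idx = np.flatnonzero(edge_mask)
    true_edges = {_pair(ids, iu[k], ju[k]) for k in edge_idx}

    non_idx = np.flatnonzero(~edge_mask)
    n_neg = min(config.n_negative_sample, non_idx.size)
    neg_idx = rng.choice(non_idx, size=n_neg, replace=False)
    neg_pairs = [_pair(ids, iu[k], ju[k]) for k in sorted(neg_idx)]

    edge_pairs = [_pair(ids, iu[k], ju[k]) for k in edge_idx]
    scored_pairs = edge_pairs + neg_pairs
    signal = np.concatenate([
        np.ones(len(edge_pairs), dtype=bool),
        np.zeros(len(neg_pairs), dtype=bool)])
    if config.null_world:
        signal[:] = False

    # --- continuous channel emissions --------------------------------------
    evidence: Dict[PairKey, Dict[str, float]] = {p: {} for p in scored_pairs}
    n_scored = len(scored_pairs)
    for ch in CONTINUOUS_CHANNELS:
        mu_pos, mu_neg, sd = config.channel_params[ch]
        present = rng.random(n_scored) < config.channel_coverage[ch]
        mu = np.where(signal, mu_pos, mu_neg)
        vals = rng.normal(mu, sd)
        for k in np.flatnonzero(present):
            evidence[scored_pairs[k]][ch] = float(vals[k])

    # --- orthology ----------------------------------------------------------
    species = [f"sp{i:02d}" for i in range(config.n_species)]
    ortholog_maps: Dict[str, OrthologMap] = {}
    for source in SOURCES:
        cov = config.source_coverage[source]
        present = rng.random((n, len(species))) < cov
        if source in config.noise_sources:
            # a noise source maps proteins to shuffled orthologs: its species
            # counts carry no information about the true graph
            assignment = rng.permutation(n)
        else:
            assignment = np.arange(n)
        orthologs: Dict[str, Set[Tuple[str, str]]] = {}
        for i in range(n):
            hits = np.flatnonzero(present[i])
            if hits.size:
                orthologs[ids[i]] = {
                    (species[s], f"{ids[assignment[i]]}|{species[s]}")
                    for s in hits}
        ortholog_maps[source] = OrthologMap(source=source, orthologs=orthologs)

    species_interactions: Set[Tuple[str, PairKey]] = set()
    p_true = config.p_or_noise if config.null_world else config.p_propagate
    for pairs, p_prop in ((edge_pairs, p_true), (neg_pairs, config.p_or_noise)):
        if not pairs or p_prop == 0:
            continue
        draws = rng.random((len(pairs), len(species))) < p_prop
        for k, pair in enumerate(pairs):
            for s in np.flatnonzero(draws[k]):
                sp = species[s]
                species_interactions.add(
                    (sp, PairKey(f"{pair.a}|{sp}", f"{pair.b}|{sp}")))

    # --- expression correlations -------------------------------------------
    datasets: Dict[str, Dict[str, object]] = {}
    for h in range(config.n_human_datasets):
        datasets[f"hum{h}"] = {"species": "human", "human": True}
    for sp in species:
        datasets[f"exp_{sp}"] = {"species": sp, "human": False}
    correlations: Dict[str, Dict[PairKey, float]] = {}
    for ds in datasets:
        present = rng.random(n_scored) < config.corr_coverage
        mu = np.where(signal, config.corr_mu_pos, config.corr_mu_neg)
        vals = np.clip(rng.normal(mu, config.corr_sd), -0.99, 0.99)
        correlations[ds] = {
            scored_pairs[k]: float(vals[k]) for k in np.flatnonzero(present)}

    # --- partner redundancy inputs -----------------------------------------
    neighbors: Dict[str, Set[str]] = {}
    for m, members in enumerate(modules):
        for pid in members:
            pool = [x for x in members if x != pid]
            take = min(config.n_struct_neighbors, len(pool))
            chosen = set()
            if take:
                idx = rng.choice(len(pool), size=take, replace=False)
                chosen = {pool[i] for i in idx}
            if config.n_noise_neighbors:
                extra = rng.choice(n, size=config.n_noise_neighbors, replace=False)
                chosen |= {ids[e] for e in extra if ids[e] != pid}
            neighbors[pid] = chosen
    nbhd = StructuralNeighborhood(neighbors=neighbors)

    def _subsample(pairs: Sequence[PairKey], frac: float) -> Set[PairKey]:
        k = int(round(frac * len(pairs)))
        if k == 0:
            return set()
        idx = rng.choice(len(pairs), size=k, replace=False)
        return {pairs[i] for i in idx}

    if config.null_world:
        known_human = _subsample(neg_pairs, config.known_human_fraction
                                 * len(edge_pairs) / max(len(neg_pairs), 1))
        known_any = _subsample(neg_pairs, config.known_any_fraction
                               * len(edge_pairs) / max(len(neg_pairs), 1))
    else:
        known_human = _subsample(edge_pairs, config.known_human_fraction)
        known_any = _subsample(edge_pairs, config.known_any_fraction)

    # --- proteins: compartments and structure flags ------------------------
    comp_choice = rng.choice(len(config.compartments), size=n,
                             p=config.compartment_probs)
    dual = rng.random(n) < config.p_dual_compartment
    second = rng.integers(0, len(config.compartments), size=n)
    has_struct = rng.random(n) < config.p_has_structure
    proteins: Dict[str, Protein] = {}
    for i, pid in enumerate(ids):
        comps = {config.compartments[comp_choice[i]]}
        if dual[i]:
            comps.add(config.compartments[(comp_choice[i] + 1 + second[i])
                                          % len(config.compartments)])
        proteins[pid] = Protein(id=pid, compartments=frozenset(comps),
                                has_structure=bool(has_struct[i]))

    # --- reference splits ---------------------------------------------------
    pos_order = rng.permutation(len(edge_pairs))
    n_train_pos = int(round(config.train_fraction * len(edge_pairs)))
    train_pos = {edge_pairs[i] for i in pos_order[:n_train_pos]}
    eval_pos = {edge_pairs[i] for i in pos_order[n_train_pos:]}

    neg_order = rng.permutation(len(neg_pairs))
    n_train_neg = int(round(config.train_fraction * len(neg_pairs)))
    train_neg = {neg_pairs[i] for i in neg_order[:n_train_neg]}
    eval_neg_scored = {neg_pairs[i] for i in neg_order[n_train_neg:]}

    quota: Dict[str, int] = {}
    eligible_counts = {c: 0 for c in config.compartments}
    for prot in proteins.values():
        if len(prot.compartments) == 1:
            eligible_counts[next(iter(prot.compartments))] += 1
    for c in config.compartments:
        quota[c] = int(config.negative_quota_frac * eligible_counts[c])
    c1, c2, c3, c4 = config.compartments
    rules = [(c1, c2), (c2, c3), (c2, c4), (c3, c4)]
    comp_neg = build_compartment_negatives(
        list(proteins.values()), quota, rules,
        seed=int(rng.integers(0, 2**31 - 1)))
    eval_neg = (comp_neg | eval_neg_scored) - true_edges - train_pos - train_neg

    refs_train = ReferenceSets(positives=train_pos, negatives=train_neg,
                               role="train")
    refs_eval = ReferenceSets(positives=eval_pos, negatives=eval_neg,
                              role="evaluate")

    # --- complexes and gene sets -------------------------------------------
    # complexes are connected units of the true graph: grow each one along
    # true edges inside its module
    adjacency: Dict[str, Set[str]] = {pid: set() for pid in ids}
    for pair in true_edges:
        adjacency[pair.a].add(pair.b)
        adjacency[pair.b].add(pair.a)
    complexes: List[ComplexDefinition] = []
    lo, hi = config.complex_size_range
    for m, members in enumerate(modules):
        in_module = set(members)
        seeds = [pid for pid in members if adjacency[pid] & in_module]
        if not seeds:
            continue
        target = min(int(rng.integers(lo, hi + 1)), len(members))
        chosen = {seeds[int(rng.integers(0, len(seeds)))]}
        while len(chosen) < target:
            frontier = sorted(
                {nb for pid in chosen for nb in adjacency[pid] & in_module}
                - chosen)
            if not frontier:
                break
            chosen.add(frontier[int(rng.integers(0, len(frontier)))])
        if len(chosen) >= 2:
            complexes.append(ComplexDefinition(id=f"CPX{m:03d}",
                                               members=frozenset(chosen)))

    gene_sets: List[GeneSet] = []
    protein_terms: Dict[str, Set[str]] = {pid: set() for pid in ids}
    for m, members in enumerate(modules):
        keep = [pid for pid in members
                if rng.random() >= config.gene_set_dropout]
        if len(keep) < 2:
            keep = members[:2]
        term = f"module{m:03d}"
        gene_sets.append(GeneSet(name=f"GS{m:03d}", term=term,
                                 members=frozenset(keep)))
        for pid in members:
            protein_terms[pid].add(term)
    sizes = [len(mod) for mod in modules]
    for j in range(config.n_decoy_sets):
        size = sizes[int(rng.integers(0, len(sizes)))]
        idx = rng.choice(n, size=min(size, n), replace=False)
        gene_sets.append(GeneSet(
            name=f"DECOY{j:03d}", term=f"decoy{j:03d}",
            members=frozenset(ids[i] for i in idx)))

    # --- interfaces and variants -------------------------------------------
    interfacial = rng.random((n, config.n_residues)) < config.interface_fraction
    q = config.variant_rate
    odds = q / (1.0 - q)
    p_int = (config.theta * odds) / (1.0 + config.theta * odds)
    p_mut = np.where(interfacial, p_int, q)
    mutated = rng.random((n, config.n_residues)) < p_mut
    interface_mask: Dict[Tuple[str, int], bool] = {}
    variants: Set[Tuple[str, int]] = set()
    for i, pid in enumerate(ids):
        for r in range(config.n_residues):
            interface_mask[(pid, r + 1)] = bool(interfacial[i, r])
            if mutated[i, r]:
                variants.add((pid, r + 1))

    return SyntheticWorld(
        config=config, proteins=proteins, modules=modules,
        true_edges=true_edges, scored_pairs=scored_pairs, evidence=evidence,
        ortholog_maps=ortholog_maps, species_interactions=species_interactions,
        correlations=correlations, dataset_manifest=datasets,
        neighborhoods=nbhd, known_human=known_human, known_any=known_any,
        refs_train=refs_train, refs_eval=refs_eval, complexes=complexes,
        gene_sets=gene_sets, protein_terms=protein_terms,
        interface_mask=interface_mask, variants=variants,
    )
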