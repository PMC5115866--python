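"""Readers and writers for the package's plain-text interchange formats.

All tabular files are tab-separated with a header row; empty cells mean
"absent".  Gene sets use GMT; trained models and world manifests use JSON.
Floats are serialised with 6 significant digits; LRs are never clipped.
"""

from __future__ import annotations

import json
import os
from typing import Dict, List, Mapping, Optional, Set, Tuple

import pandas as pd

from .core import (CombinedScore, InputError, PairKey, Protein, ReferenceSets,
                   classify_reliable)
from .evaluation import ComplexDefinition
from .gsea import EnrichmentResult, GeneSet
from .orthology import OrthologMap
from .partner_redundancy import StructuralNeighborhood
from .pipeline import TrainedModels
from .snp import ContingencyTable
from .synthetic import SyntheticWorld, WorldConfig

FLOAT_FMT = "%.6g"


def _read_tsv(path: str, required: List[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={c: str for c in required
                                                if c.endswith(("_id", "_a", "_b", "_1", "_2"))})
    except FileNotFoundError:
        raise InputError(f"{path}: file not found")
    except Exception as exc:  # malformed TSV
        raise InputError(f"{path}: cannot parse ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def check_overwrite(path: str, force: bool) -> None:
    if os.path.exists(path) and not force:
        raise InputError(f"{path} exists; pass --force to overwrite")


# --- evidence ---------------------------------------------------------------

EVIDENCE_CHANNELS = ("SM", "PrP", "GO", "PP")


def read_evidence(path: str) -> Dict[PairKey, Dict[str, float]]:
    df = _read_tsv(path, ["protein_a", "protein_b"])
    channels = [c for c in df.columns if c in EVIDENCE_CHANNELS]
    out: Dict[PairKey, Dict[str, float]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            pair = PairKey(str(row.protein_a), str(row.protein_b))
        except InputError as exc:
            raise InputError(f"{path}, line {i}: {exc}") from exc
        scores = {}
        for ch in channels:
            v = getattr(row, ch)
            if pd.notna(v):
                scores[ch] = float(v)
        out[pair] = scores
    return out


def write_evidence(evidence: Mapping[PairKey, Mapping[str, float]],
                   path: str) -> None:
    rows = []
    for pair in sorted(evidence, key=lambda p: (p.a, p.b)):
        row = {"protein_a": pair.a, "protein_b": pair.b}
        for ch in EVIDENCE_CHANNELS:
            row[ch] = evidence[pair].get(ch, None)
        rows.append(row)
    _write_tsv(pd.DataFrame(rows, columns=["protein_a", "protein_b",
                                           *EVIDENCE_CHANNELS]), path)


# --- pair lists -------------------------------------------------------------


def read_pairs(path: str) -> Set[PairKey]:
    df = _read_tsv(path, ["protein_a", "protein_b"])
    pairs = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            pairs.add(PairKey(str(row.protein_a), str(row.protein_b)))
        except InputError as exc:
            raise InputError(f"{path}, line {i}: {exc}") from exc
    return pairs


def write_pairs(pairs, path: str) -> None:
    rows = [{"protein_a": p.a, "protein_b": p.b}
            for p in sorted(pairs, key=lambda p: (p.a, p.b))]
    _write_tsv(pd.DataFrame(rows, columns=["protein_a", "protein_b"]), path)


def read_reference_sets(pos_path: str, neg_path: str,
                        role: str) -> ReferenceSets:
    return ReferenceSets(positives=read_pairs(pos_path),
                         negatives=read_pairs(neg_path), role=role)


# --- orthology --------------------------------------------------------------


def read_ortholog_maps(path: str) -> Dict[str, OrthologMap]:
    df = _read_tsv(path, ["source", "protein_id", "species", "ortholog_id"])
    maps: Dict[str, OrthologMap] = {}
    for row in df.itertuples(index=False):
        m = maps.setdefault(str(row.source), OrthologMap(source=str(row.source)))
        m.orthologs.setdefault(str(row.protein_id), set()).add(
            (str(row.species), str(row.ortholog_id)))
    return maps


def write_ortholog_maps(maps: Mapping[str, OrthologMap], path: str) -> None:
    rows = []
    for source in sorted(maps):
        for pid in sorted(maps[source].orthologs):
            for species, oid in sorted(maps[source].orthologs[pid]):
                rows.append({"source": source, "protein_id": pid,
                             "species": species, "ortholog_id": oid})
    _write_tsv(pd.DataFrame(rows, columns=["source", "protein_id", "species",
                                           "ortholog_id"]), path)


def read_species_interactions(path: str) -> Set[Tuple[str, PairKey]]:
    df = _read_tsv(path, ["species", "protein_1", "protein_2"])
    out = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.add((str(row.species), PairKey(str(row.protein_1),
                                               str(row.protein_2))))
        except InputError as exc:
            raise InputError(f"{path}, line {i}: {exc}") from exc
    return out


def write_species_interactions(interactions, path: str) -> None:
    rows = [{"species": sp, "protein_1": p.a, "protein_2": p.b}
            for sp, p in sorted(interactions, key=lambda x: (x[0], x[1].a, x[1].b))]
    _write_tsv(pd.DataFrame(rows, columns=["species", "protein_1",
                                           "protein_2"]), path)


# --- expression -------------------------------------------------------------


def read_correlations(path: str) -> Dict[str, Dict[PairKey, float]]:
    df = _read_tsv(path, ["dataset", "protein_1", "protein_2", "pearson_r"])
    out: Dict[str, Dict[PairKey, float]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            pair = PairKey(str(row.protein_1), str(row.protein_2))
        except InputError as exc:
            raise InputError(f"{path}, line {i}: {exc}") from exc
        out.setdefault(str(row.dataset), {})[pair] = float(row.pearson_r)
    return out


def write_correlations(correlations: Mapping[str, Mapping[PairKey, float]],
                       path: str) -> None:
    rows = []
    for ds in sorted(correlations):
        for pair in sorted(correlations[ds], key=lambda p: (p.a, p.b)):
            rows.append({"dataset": ds, "protein_1": pair.a,
                         "protein_2": pair.b,
                         "pearson_r": correlations[ds][pair]})
    _write_tsv(pd.DataFrame(rows, columns=["dataset", "protein_1", "protein_2",
                                           "pearson_r"]), path)


def read_dataset_manifest(path: str) -> Dict[str, Dict[str, object]]:
    df = _read_tsv(path, ["dataset", "species", "human"])
    return {str(r.dataset): {"species": str(r.species),
                             "human": bool(int(r.human))}
            for r in df.itertuples(index=False)}


def write_dataset_manifest(manifest: Mapping[str, Mapping[str, object]],
                           path: str) -> None:
    rows = [{"dataset": ds, "species": meta["species"],
             "human": int(bool(meta["human"]))}
            for ds, meta in sorted(manifest.items())]
    _write_tsv(pd.DataFrame(rows, columns=["dataset", "species", "human"]), path)


# --- partner redundancy -----------------------------------------------------


def read_neighborhoods(path: str) -> StructuralNeighborhood:
    df = _read_tsv(path, ["protein_id", "neighbor_id"])
    nb: Dict[str, Set[str]] = {}
    for row in df.itertuples(index=False):
        nb.setdefault(str(row.protein_id), set()).add(str(row.neighbor_id))
    return StructuralNeighborhood(neighbors=nb)


def write_neighborhoods(nbhd: StructuralNeighborhood, path: str) -> None:
    rows = [{"protein_id": pid, "neighbor_id": nid}
            for pid in sorted(nbhd.neighbors)
            for nid in sorted(nbhd.neighbors[pid])]
    _write_tsv(pd.DataFrame(rows, columns=["protein_id", "neighbor_id"]), path)


# --- proteins, complexes, gene sets ----------------------------------------


def read_proteins(path: str) -> Dict[str, Protein]:
    df = _read_tsv(path, ["protein_id", "compartments", "has_structure"])
    out = {}
    for row in df.itertuples(index=False):
        comps = frozenset(str(row.compartments).split(",")) \
            if pd.notna(row.compartments) and str(row.compartments) else frozenset()
        out[str(row.protein_id)] = Protein(
            id=str(row.protein_id), compartments=comps,
            has_structure=bool(int(row.has_structure)))
    return out


def write_proteins(proteins: Mapping[str, Protein], path: str) -> None:
    rows = [{"protein_id": p.id,
             "compartments": ",".join(sorted(p.compartments)),
             "has_structure": int(p.has_structure)}
            for p in sorted(proteins.values(), key=lambda p: p.id)]
    _write_tsv(pd.DataFrame(rows, columns=["protein_id", "compartments",
                                           "has_structure"]), path)


def read_complexes(path: str) -> List[ComplexDefinition]:
    df = _read_tsv(path, ["complex_id", "member_id"])
    members: Dict[str, Set[str]] = {}
    for row in df.itertuples(index=False):
        members.setdefault(str(row.complex_id), set()).add(str(row.member_id))
    return [ComplexDefinition(id=cid, members=frozenset(ms))
            for cid, ms in sorted(members.items())]


def write_complexes(complexes, path: str) -> None:
    rows = [{"complex_id": c.id, "member_id": m}
            for c in sorted(complexes, key=lambda c: c.id)
            for m in sorted(c.members)]
    _write_tsv(pd.DataFrame(rows, columns=["complex_id", "member_id"]), path)


def read_gmt(path: str) -> List[GeneSet]:
    sets = []
    try:
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise InputError(
                        f"{path}, line {i}: GMT rows need name, term and >= 1 member")
                sets.append(GeneSet(name=parts[0], term=parts[1],
                                    members=frozenset(parts[2:])))
    except OSError as exc:
        raise InputError(f"{path}: {exc}") from exc
    return sets


def write_gmt(gene_sets, path: str) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.term, *sorted(gs.members)]) + "\n")


def read_protein_terms(path: str) -> Dict[str, Set[str]]:
    df = _read_tsv(path, ["protein_id", "term"])
    out: Dict[str, Set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.protein_id), set()).add(str(row.term))
    return out


def write_protein_terms(terms: Mapping[str, Set[str]], path: str) -> None:
    rows = [{"protein_id": pid, "term": t}
            for pid in sorted(terms) for t in sorted(terms[pid])]
    _write_tsv(pd.DataFrame(rows, columns=["protein_id", "term"]), path)


# --- interfaces and variants ------------------------------------------------


def read_interfaces(path: str) -> Dict[Tuple[str, int], bool]:
    """Interface mask, OR-reducing duplicate (protein, residue) rows."""
    df = _read_tsv(path, ["protein_id", "residue_index", "interfacial"])
    mask: Dict[Tuple[str, int], bool] = {}
    for row in df.itertuples(index=False):
        key = (str(row.protein_id), int(row.residue_index))
        mask[key] = mask.get(key, False) or bool(int(row.interfacial))
    return mask


def write_interfaces(mask: Mapping[Tuple[str, int], bool], path: str) -> None:
    rows = [{"protein_id": p, "residue_index": r, "interfacial": int(v)}
            for (p, r), v in sorted(mask.items())]
    _write_tsv(pd.DataFrame(rows, columns=["protein_id", "residue_index",
                                           "interfacial"]), path)


def read_variants(path: str,
                  variant_class: Optional[str] = None) -> Set[Tuple[str, int]]:
    df = _read_tsv(path, ["protein_id", "residue_index", "class"])
    if variant_class is not None:
        df = df[df["class"].astype(str) == variant_class]
    return {(str(p), int(r))
            for p, r in zip(df["protein_id"], df["residue_index"])}


def write_variants(variants, path: str, variant_class: str = "disease") -> None:
    rows = [{"protein_id": p, "residue_index": r, "class": variant_class}
            for (p, r) in sorted(variants)]
    _write_tsv(pd.DataFrame(rows, columns=["protein_id", "residue_index",
                                           "class"]), path)


def read_contingency_counts(path: str) -> ContingencyTable:
    df = _read_tsv(path, ["n11", "n10", "n01", "n00"])
    if len(df) != 1:
        raise InputError(f"{path}: expected exactly one row of counts")
    r = df.iloc[0]
    return ContingencyTable(int(r.n11), int(r.n10), int(r.n01), int(r.n00))


# --- scores and models ------------------------------------------------------


def write_scores(scores: Mapping[PairKey, CombinedScore], path: str,
                 threshold: float = 600.0) -> None:
    from .core import CHANNELS
    rows = []
    for pair in sorted(scores, key=lambda p: (p.a, p.b)):
        s = scores[pair]
        row = {"protein_a": pair.a, "protein_b": pair.b}
        for ch in CHANNELS:
            row[f"lr_{ch}"] = s.channel_lrs.get(ch, None)
        row["lr_total"] = s.lr_total
        row["lr_structural"] = s.lr_structural
        row["reliable"] = int(classify_reliable(s, threshold))
        rows.append(row)
    cols = ["protein_a", "protein_b",
            *[f"lr_{ch}" for ch in ("SM", "PrP", "PR", "GO", "PP", "OR", "EP")],
            "lr_total", "lr_structural", "reliable"]
    _write_tsv(pd.DataFrame(rows, columns=cols), path)


def read_scores(path: str) -> Dict[PairKey, float]:
    """Total LR per pair from a scores TSV."""
    df = _read_tsv(path, ["protein_a", "protein_b", "lr_total"])
    out = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out[PairKey(str(row.protein_a), str(row.protein_b))] = float(row.lr_total)
        except InputError as exc:
            raise InputError(f"{path}, line {i}: {exc}") from exc
    return out


def save_models(models: TrainedModels, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(models.to_dict(), fh, indent=1)


def load_models(path: str) -> TrainedModels:
    try:
        with open(path) as fh:
            return TrainedModels.from_dict(json.load(fh))
    except (OSError, KeyError, ValueError) as exc:
        raise InputError(f"{path}: cannot load models ({exc})") from exc


def write_enrichment_report(results: List[EnrichmentResult], path: str) -> None:
    rows = [{"gene_set": r.name, "term": r.term, "es": r.es, "p": r.p,
             "q": r.q, "rank": r.rank, "enriched": int(r.enriched)}
            for r in results]
    _write_tsv(pd.DataFrame(rows, columns=["gene_set", "term", "es", "p", "q",
                                           "rank", "enriched"]), path)


def write_curve(points, path: str, columns=("threshold", "fraction")) -> None:
    _write_tsv(pd.DataFrame(points, columns=list(columns)), path)


# --- world bundle -----------------------------------------------------------


def write_world(world: SyntheticWorld, outdir: str, force: bool = False) -> None:
    """Emit the whole synthetic bundle as the TSV/GMT/JSON dialects above."""
    os.makedirs(outdir, exist_ok=True)
    paths = {name: os.path.join(outdir, name) for name in (
        "evidence.tsv", "orthologs.tsv", "species_interactions.tsv",
        "correlations.tsv", "datasets.tsv", "neighborhoods.tsv",
        "known_human.tsv", "known_any.tsv", "proteins.tsv",
        "train_positives.tsv", "train_negatives.tsv",
        "eval_positives.tsv", "eval_negatives.tsv",
        "complexes.tsv", "gene_sets.gmt", "protein_terms.tsv",
        "interfaces.tsv", "variants.tsv", "true_edges.tsv", "manifest.json")}
    for p in paths.values():
        check_overwrite(p, force)
    write_evidence(world.evidence, paths["evidence.tsv"])
    write_ortholog_maps(world.ortholog_maps, paths["orthologs.tsv"])
    write_species_interactions(world.species_interactions,
                               paths["species_interactions.tsv"])
    write_correlations(world.correlations, paths["correlations.tsv"])
    write_dataset_manifest(world.dataset_manifest, paths["datasets.tsv"])
    write_neighborhoods(world.neighborhoods, paths["neighborhoods.tsv"])
    write_pairs(world.known_human, paths["known_human.tsv"])
    write_pairs(world.known_any, paths["known_any.tsv"])
    write_proteins(world.proteins, paths["proteins.tsv"])
    write_pairs(world.refs_train.positives, paths["train_positives.tsv"])
    write_pairs(world.refs_train.negatives, paths["train_negatives.tsv"])
    write_pairs(world.refs_eval.positives, paths["eval_positives.tsv"])
    write_pairs(world.refs_eval.negatives, paths["eval_negatives.tsv"])
    write_complexes(world.complexes, paths["complexes.tsv"])
    write_gmt(world.gene_sets, paths["gene_sets.gmt"])
    write_protein_terms(world.protein_terms, paths["protein_terms.tsv"])
    write_interfaces(world.interface_mask, paths["interfaces.tsv"])
    write_variants(world.variants, paths["variants.tsv"])
    write_pairs(world.true_edges, paths["true_edges.tsv"])
    import dataclasses as _dc
    with open(paths["manifest.json"], "w") as fh:
        json.dump({"config": _dc.asdict(world.config),
                   "seed": world.config.seed}, fh, indent=1, default=list)


class WorldData:
    """Lazily grouped on-disk world bundle, shaped like SyntheticWorld."""

    def __init__(self, directory: str):
        j = lambda name: os.path.join(directory, name)
        self.evidence = read_evidence(j("evidence.tsv"))
        self.ortholog_maps = read_ortholog_maps(j("orthologs.tsv"))
        self.species_interactions = read_species_interactions(
            j("species_interactions.tsv"))
        self.correlations = read_correlations(j("correlations.tsv"))
        self.dataset_manifest = read_dataset_manifest(j("datasets.tsv"))
        self.neighborhoods = read_neighborhoods(j("neighborhoods.tsv"))
        self.known_human = read_pairs(j("known_human.tsv"))
        self.known_any = read_pairs(j("known_any.tsv"))
        self.proteins = read_proteins(j("proteins.tsv"))
        self.refs_train = read_reference_sets(
            j("train_positives.tsv"), j("train_negatives.tsv"), "train")
        self.refs_eval = read_reference_sets(
            j("eval_positives.tsv"), j("eval_negatives.tsv"), "evaluate")
        self.complexes = read_complexes(j("complexes.tsv"))
        self.gene_sets = read_gmt(j("gene_sets.gmt"))
        self.protein_terms = read_protein_terms(j("protein_terms.tsv"))
        self.interface_mask = read_interfaces(j("interfaces.tsv"))
        self.variants = read_variants(j("variants.tsv"))
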