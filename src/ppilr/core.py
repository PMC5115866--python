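"""Core domain types, binned likelihood-ratio estimation, and naive-Bayes combination.

Evidence for a candidate protein pair arrives through independent channels.
Each channel's raw score is mapped to a bin, the bin to a likelihood ratio
(LR) estimated from labelled reference sets, and the per-channel LRs are
multiplied into a single combined LR.  The two structure-based channels
(``SM`` and ``PrP``) describe mutually exclusive interaction geometries, so
only the larger of the two enters the product.
"""

from __future__ import annotations

import bisect
import itertools
import math
from dataclasses import dataclass, field
from typing import Any, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

#: Recognised evidence channels, in combination order.
CHANNELS = ("SM", "PrP", "PR", "GO", "PP", "OR", "EP")

#: Channels whose evidence implies a direct physical contact.
STRUCTURAL_CHANNELS = ("SM", "PrP", "PR")

#: Default combined-LR cutoff for calling a prediction reliable.
DEFAULT_RELIABLE_LR = 600.0


class PpilrError(Exception):
    """Base class for all package errors."""


class InputError(PpilrError):
    """Malformed or out-of-domain input."""


class TrainingError(PpilrError):
    """Reference data insufficient to train a model."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class PairKey:
    """Unordered pair of protein ids; canonicalised lexicographically."""

    a: str
    b: str

    def __post_init__(self) -> None:
        if not self.a or not self.b:
            raise InputError("protein ids must be non-empty")
        if self.a == self.b:
            raise InputError(f"self-pair not allowed: {self.a!r}")
        if self.a > self.b:
            a, b = self.a, self.b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)

    def other(self, pid: str) -> str:
        """Return the partner of ``pid`` in this pair."""
        if pid == self.a:
            return self.b
        if pid == self.b:
            return self.a
        raise InputError(f"{pid!r} is not a member of {self}")

    def __iter__(self):
        return iter((self.a, self.b))


@dataclass(frozen=True)
class Protein:
    id: str
    compartments: frozenset = frozenset()
    has_structure: bool = True

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("protein id must be non-empty")
        object.__setattr__(self, "compartments", frozenset(self.compartments))


@dataclass
class EvidenceVector:
    """Raw per-channel scores for one pair; absent channels are simply missing.

    ``OR`` holds an :class:`~ppilr.orthology.OrthologyVector`, ``PR`` a
    :class:`~ppilr.partner_redundancy.PartnerRedundancyFeatures`; the other
    channels are plain reals.  Absence is encoded by omission, never by 0.
    """

    pair: PairKey
    scores: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ch in self.scores:
            if ch not in CHANNELS:
                raise InputError(f"unknown evidence channel {ch!r}")
        if not self.scores:
            raise InputError(f"pair {self.pair} has no evidence in any channel")

    def get(self, channel: str, default=None):
        return self.scores.get(channel, default)

    def __contains__(self, channel: str) -> bool:
        return channel in self.scores


@dataclass
class ReferenceSets:
    """Labelled positive and negative pair collections with a usage role."""

    positives: set
    negatives: set
    role: str = "train"

    def __post_init__(self) -> None:
        if self.role not in ("train", "evaluate"):
            raise InputError(f"role must be 'train' or 'evaluate', got {self.role!r}")
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise InputError(
                f"positives and negatives overlap on {len(overlap)} pairs"
            )


# ---------------------------------------------------------------------------
# Bin partitions
# ---------------------------------------------------------------------------


class BinPartition:
    """Abstract partition of a channel's score domain into bins."""

    labels: List[Any]

    def __len__(self) -> int:
        return len(self.labels)

    def assign(self, score) -> int:
        """Return the index of the bin containing ``score``; raise InputError otherwise."""
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError

    @staticmethod
    def from_dict(d: dict) -> "BinPartition":
        kind = d["kind"]
        if kind == "categorical":
            return CategoricalBins.from_dict(d)
        if kind == "interval":
            return IntervalBins.from_dict(d)
        if kind == "grid":
            return GridBins.from_dict(d)
        raise InputError(f"unknown bin partition kind {kind!r}")


def _freeze(x):
    if isinstance(x, list):
        return tuple(_freeze(v) for v in x)
    return x


class CategoricalBins(BinPartition):
    """One bin per discrete category (e.g. per orthology vector)."""

    def __init__(self, categories: Iterable[Any]):
        self.labels = [_freeze(c) for c in categories]
        if len(set(self.labels)) != len(self.labels):
            raise InputError("duplicate categories in bin partition")
        self._index = {c: i for i, c in enumerate(self.labels)}

    def assign(self, score) -> int:
        key = _freeze(score)
        if key not in self._index:
            raise InputError(f"score {score!r} does not map to any bin")
        return self._index[key]

    def to_dict(self) -> dict:
        return {"kind": "categorical", "categories": [
            list(c) if isinstance(c, tuple) else c for c in self.labels]}

    @classmethod
    def from_dict(cls, d: dict) -> "CategoricalBins":
        return cls(d["categories"])


class IntervalBins(BinPartition):
    """Contiguous numeric bins [e0,e1), [e1,e2), ... [e_{n-1}, e_n]."""

    def __init__(self, edges: Sequence[float]):
        edges = [float(e) for e in edges]
        if len(edges) < 2 or any(x >= y for x, y in zip(edges, edges[1:])):
            raise InputError("edges must be strictly increasing with >= 2 entries")
        self.edges = edges
        self.labels = list(zip(edges[:-1], edges[1:]))

    @classmethod
    def from_quantiles(cls, values: Sequence[float], n_bins: int = 10) -> "IntervalBins":
        """Equal-frequency bins of a training pool, open-ended at both extremes."""
        values = np.asarray(list(values), dtype=float)
        if values.size == 0:
            raise TrainingError("cannot build quantile bins from an empty pool")
        qs = np.quantile(values, np.linspace(0.0, 1.0, n_bins + 1))
        inner = sorted(set(qs[1:-1].tolist()))
        return cls([-math.inf] + inner + [math.inf])

    def assign(self, score) -> int:
        x = float(score)
        if math.isnan(x):
            raise InputError("NaN score cannot be binned")
        if x < self.edges[0] or x > self.edges[-1]:
            raise InputError(f"score {x} outside bin range [{self.edges[0]}, {self.edges[-1]}]")
        if x == self.edges[-1]:
            return len(self.labels) - 1
        return bisect.bisect_right(self.edges, x) - 1

    def to_dict(self) -> dict:
        return {"kind": "interval",
                "edges": [repr(e) if math.isinf(e) else e for e in self.edges]}

    @classmethod
    def from_dict(cls, d: dict) -> "IntervalBins":
        return cls([float(e) for e in d["edges"]])


class GridBins(BinPartition):
    """Cartesian product of per-axis interval partitions (vector-of-ranges bins)."""

    def __init__(self, axes: Sequence[IntervalBins]):
        self.axes = list(axes)
        self.labels = [tuple(combo) for combo in itertools.product(
            *(ax.labels for ax in self.axes))]

    def assign(self, score) -> int:
        vec = tuple(score)
        if len(vec) != len(self.axes):
            raise InputError(
                f"expected a {len(self.axes)}-component score, got {score!r}")
        idx = 0
        for ax, x in zip(self.axes, vec):
            idx = idx * len(ax) + ax.assign(x)
        return idx

    def to_dict(self) -> dict:
        return {"kind": "grid", "axes": [ax.to_dict() for ax in self.axes]}

    @classmethod
    def from_dict(cls, d: dict) -> "GridBins":
        return cls([IntervalBins.from_dict(a) for a in d["axes"]])


# ---------------------------------------------------------------------------
# Binned LR model
# ---------------------------------------------------------------------------


@dataclass
class BinnedLRModel:
    """Per-channel bin partition with one trained LR per bin.

    ``lr[b] = P(bin b | positive) / P(bin b | negative)`` with an optional
    symmetric pseudo-count; training counts are retained so that downstream
    scoring can check per-bin support before trusting an LR.
    """

    channel: str
    bins: BinPartition
    lr: np.ndarray
    pos_counts: np.ndarray
    neg_counts: np.ndarray
    pseudo_count: float = 0.0

    def lookup(self, score) -> float:
        return float(self.lr[self.bins.assign(score)])

    def support(self, score) -> int:
        """Total (positive + negative) training pairs in the score's bin."""
        idx = self.bins.assign(score)
        return int(self.pos_counts[idx] + self.neg_counts[idx])

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "bins": self.bins.to_dict(),
            "lr": [repr(v) if math.isinf(v) else float(v) for v in self.lr],
            "pos_counts": [int(v) for v in self.pos_counts],
            "neg_counts": [int(v) for v in self.neg_counts],
            "pseudo_count": self.pseudo_count,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinnedLRModel":
        return cls(
            channel=d["channel"],
            bins=BinPartition.from_dict(d["bins"]),
            lr=np.array([float(v) for v in d["lr"]]),
            pos_counts=np.asarray(d["pos_counts"], dtype=np.int64),
            neg_counts=np.asarray(d["neg_counts"], dtype=np.int64),
            pseudo_count=float(d["pseudo_count"]),
        )


def fit_binned_lr(
    channel_scores: Mapping[PairKey, Any],
    refs: ReferenceSets,
    bins: BinPartition,
    pseudo_count: float = 0.5,
    channel: str = "",
) -> BinnedLRModel:
    """Train one channel's bin->LR table from labelled reference pairs.

    Only reference pairs that actually carry evidence for the channel
    contribute; the LR of a bin is the (pseudo-counted) fraction of evidence-
    bearing positives falling in it divided by the same fraction among
    negatives.
    """
    if pseudo_count < 0:
        raise InputError("pseudo_count must be nonnegative")
    if not refs.positives or not refs.negatives:
        raise TrainingError("both positive and negative reference pairs are required")

    n_bins = len(bins)
    pos_counts = np.zeros(n_bins, dtype=np.int64)
    neg_counts = np.zeros(n_bins, dtype=np.int64)
    for pairs, counts in ((refs.positives, pos_counts), (refs.negatives, neg_counts)):
        for pair in pairs:
            if pair not in channel_scores:
                continue  # no evidence for this channel -> excluded from counts
            try:
                idx = bins.assign(channel_scores[pair])
            except InputError as exc:
                raise InputError(f"pair {pair}: {exc}") from exc
            counts[idx] += 1

    n_pos = int(pos_counts.sum())
    n_neg = int(neg_counts.sum())
    if pseudo_count == 0 and (n_pos == 0 or n_neg == 0):
        raise TrainingError(
            f"channel {channel or '?'}: no evidence-bearing positives or negatives")

    p_pos = (pos_counts + pseudo_count) / (n_pos + n_bins * pseudo_count)
    p_neg = (neg_counts + pseudo_count) / (n_neg + n_bins * pseudo_count)
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = p_pos / p_neg
    lr[(p_pos == 0) & (p_neg == 0)] = 1.0  # empty bin: neutral
    return BinnedLRModel(channel=channel, bins=bins, lr=lr,
                         pos_counts=pos_counts, neg_counts=neg_counts,
                         pseudo_count=pseudo_count)


def lookup_lr(model: BinnedLRModel, score) -> float:
    """LR of the bin that ``score`` falls in."""
    return model.lookup(score)


# ---------------------------------------------------------------------------
# Naive-Bayes combination
# ---------------------------------------------------------------------------


@dataclass
class CombinedScore:
    pair: Optional[PairKey]
    lr_total: float
    lr_structural: float
    channel_lrs: Dict[str, float] = field(default_factory=dict)


def combine_evidence(
    per_channel_lrs: Mapping[str, Optional[float]],
    pair: Optional[PairKey] = None,
    square_pr: bool = False,
) -> CombinedScore:
    """Multiply per-channel LRs into a combined score.

    Absent channels (missing key or None) contribute a neutral factor of 1.
    The SM and PrP channels enter through their maximum.  ``square_pr``
    applies the partner-redundancy factor twice (off by default).
    """
    lrs: Dict[str, float] = {}
    for ch, v in per_channel_lrs.items():
        if ch not in CHANNELS:
            raise InputError(f"unknown evidence channel {ch!r}")
        if v is None:
            continue
        v = float(v)
        if v < 0:
            raise InputError(f"channel {ch}: negative LR {v}")
        lrs[ch] = v

    struct_candidates = [lrs[ch] for ch in ("SM", "PrP") if ch in lrs]
    max_sm_prp = max(struct_candidates) if struct_candidates else 1.0
    pr = lrs.get("PR", 1.0)
    lr_structural = max_sm_prp * pr
    total = max_sm_prp * pr * (pr if square_pr else 1.0)
    for ch in ("GO", "PP", "OR", "EP"):
        total *= lrs.get(ch, 1.0)
    return CombinedScore(pair=pair, lr_total=total,
                         lr_structural=lr_structural, channel_lrs=lrs)


def classify_reliable(score, threshold: float = DEFAULT_RELIABLE_LR) -> bool:
    """True iff the combined LR strictly exceeds ``threshold``."""
    lr = score.lr_total if isinstance(score, CombinedScore) else float(score)
    return lr > threshold
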