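"""Variant-interface enrichment: 2x2 contingency counts, odds ratio, Z-score.

Every residue of every variant-bearing protein is cross-classified as
interfacial/non-interfacial and mutated/unmutated; enrichment of variants
in interfaces is summarised by the cross-product odds ratio with a log-odds
standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Set, Tuple

from .core import InputError


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 residue counts: first index interfacial, second mutated.

    n11: interfacial mutated, n10: non-interfacial mutated,
    n01: interfacial unmutated, n00: non-interfacial unmutated.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        for name in ("n11", "n10", "n01", "n00"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be nonnegative")

    @property
    def n_mutated(self) -> int:
        return self.n11 + self.n10

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


def build_table(
    interface_mask: Mapping[Tuple[str, int], bool],
    variant_positions: Iterable[Tuple[str, int]],
) -> ContingencyTable:
    """Classify all residues of variant-bearing proteins into the four cells.

    ``interface_mask`` is the residue universe: (protein, 1-based residue
    index) -> interfacial flag, already OR-reduced over interaction partners.
    Only proteins that carry at least one variant contribute residues.
    """
    variants: Set[Tuple[str, int]] = set(variant_positions)
    for pos in variants:
        if pos not in interface_mask:
            raise InputError(
                f"variant at unknown residue {pos[1]} of protein {pos[0]!r}")
    mutated_proteins = {p for p, _ in variants}
    n11 = n10 = n01 = n00 = 0
    for (protein, residue), interfacial in interface_mask.items():
        if protein not in mutated_proteins:
            continue
        mutated = (protein, residue) in variants
        if interfacial:
            if mutated:
                n11 += 1
            else:
                n01 += 1
        elif mutated:
            n10 += 1
        else:
            n00 += 1
    return ContingencyTable(n11, n10, n01, n00)


def odds_ratio(t: ContingencyTable, haldane: bool = False) -> float:
    """Cross-product odds ratio (n11*n00)/(n10*n01).

    ``haldane`` adds 0.5 to every cell (use for tables with zero cells).
    """
    k = 0.5 if haldane else 0.0
    num = (t.n11 + k) * (t.n00 + k)
    den = (t.n10 + k) * (t.n01 + k)
    if den == 0:
        raise InputError(
            "zero denominator cell (n10 or n01); consider haldane=True")
    return num / den


def z_score(t: ContingencyTable, haldane: bool = False) -> float:
    """Z = ln(OR) / SE with SE = sqrt(sum of reciprocal cells)."""
    k = 0.5 if haldane else 0.0
    cells = [t.n11 + k, t.n10 + k, t.n01 + k, t.n00 + k]
    if any(c == 0 for c in cells):
        raise InputError("all four cells must be positive; consider haldane=True")
    se = math.sqrt(sum(1.0 / c for c in cells))
    return math.log(odds_ratio(t, haldane=haldane)) / se


def log_odds_se(t: ContingencyTable, haldane: bool = False) -> float:
    """Standard error of ln(OR): sqrt(1/n11 + 1/n10 + 1/n01 + 1/n00)."""
    k = 0.5 if haldane else 0.0
    cells = [t.n11 + k, t.n10 + k, t.n01 + k, t.n00 + k]
    if any(c == 0 for c in cells):
        raise InputError("all four cells must be positive; consider haldane=True")
    return math.sqrt(sum(1.0 / c for c in cells))
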