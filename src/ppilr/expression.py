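"""Cross-species expression-correlation score.

Per-dataset Pearson correlations for a pair's (orthologous) transcripts are
consolidated with a consistency-rewarding product rule: agreeing datasets
push the score towards +/-1 while the majority sign decides which side is
kept.  Human and non-human consolidated scores are then blended with a
damping weight ``w`` applied to the cross-species side.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

from .core import InputError

#: Damping weight applied to the non-human consolidated score.
DEFAULT_W = 0.6


def s_pos(coeffs: Sequence[float]) -> float:
    """Consolidate strictly positive correlations: ``1 - prod(1 - c_j)``."""
    if not coeffs:
        raise InputError("s_pos requires at least one coefficient")
    prod = 1.0
    for c in coeffs:
        if not 0.0 < c <= 1.0:
            raise InputError(f"s_pos coefficient out of (0, 1]: {c}")
        prod *= 1.0 - c
    return 1.0 - prod


def s_neg(coeffs: Sequence[float]) -> float:
    """Consolidate strictly negative correlations; sign-mirror of :func:`s_pos`."""
    if not coeffs:
        raise InputError("s_neg requires at least one coefficient")
    prod = 1.0
    for c in coeffs:
        if not -1.0 <= c < 0.0:
            raise InputError(f"s_neg coefficient out of [-1, 0): {c}")
        prod *= 1.0 - abs(c)
    return -(1.0 - prod)


def s_orth(coeffs: Sequence[float]) -> Optional[float]:
    """Majority-sign consolidation of one-correlation-per-species inputs.

    Zero coefficients are dropped; ties go to the positive side.  Returns
    None when no signed coefficients remain (evidence absent).
    """
    pos = [c for c in coeffs if c > 0.0]
    neg = [c for c in coeffs if c < 0.0]
    if not pos and not neg:
        return None
    if len(pos) >= len(neg):
        return s_pos(pos) if pos else s_neg(neg)
    return s_neg(neg)


def coxs(s_human: float, s_orth_val: float, w: float = DEFAULT_W) -> float:
    """Blend human and cross-species consolidated scores.

    Same-signed inputs reinforce (with the non-human side damped by ``w``);
    mixed signs defer to the nonnegative member.
    """
    if not 0.0 <= w <= 1.0:
        raise InputError(f"w must be in [0, 1], got {w}")
    for name, v in (("s_human", s_human), ("s_orth", s_orth_val)):
        if not -1.0 <= v <= 1.0 or math.isnan(v):
            raise InputError(f"{name} out of [-1, 1]: {v}")
    if s_human >= 0.0 and s_orth_val >= 0.0:
        return 1.0 - (1.0 - s_human) * (1.0 - s_orth_val * w)
    if s_human >= 0.0 > s_orth_val:
        return s_human
    if s_orth_val >= 0.0 > s_human:
        return s_orth_val
    return -(1.0 - (1.0 - abs(s_human)) * (1.0 - abs(s_orth_val) * w))


def ep_score(
    human_coeffs: Sequence[float],
    ortholog_coeffs: Sequence[float],
    w: float = DEFAULT_W,
) -> Optional[float]:
    """Expression-profile score for a pair, or None when no data exists.

    ``human_coeffs`` come from the human datasets, ``ortholog_coeffs`` carry
    one correlation per non-human species.  When only one side has data its
    consolidated score is returned unblended.
    """
    sh = s_orth(human_coeffs)
    so = s_orth(ortholog_coeffs)
    if sh is None and so is None:
        return None
    if sh is None:
        return so
    if so is None:
        return sh
    return coxs(sh, so, w)
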