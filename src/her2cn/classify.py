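"""FISH average copy-number scoring and ASCO/CAP 2013 HER2 classification.

The copy-number route of the ASCO/CAP 2013 in-situ-hybridization guideline
classifies a tumor by average ERBB2 copies per cell alone: negative below
4, equivocal from 4 up to (but excluding) 6, positive at 6 or more.  The
same cutoffs are applied to FISH signal counts and to MIP-array copy-number
estimates.  The dual-probe ERBB2/CEP17 ratio route is intentionally not
implemented here.
"""

from __future__ import annotations

import math

from .datamodel import FishObservation, Her2Class

__all__ = [
    "fish_average_cn",
    "classify_cn",
    "round_fish_cn",
    "round_mip_cn",
    "NEGATIVE_EQUIVOCAL_CUTOFF",
    "EQUIVOCAL_POSITIVE_CUTOFF",
]

#: ASCO/CAP 2013 copy-number cutoffs (copies per cell).
NEGATIVE_EQUIVOCAL_CUTOFF = 4.0
EQUIVOCAL_POSITIVE_CUTOFF = 6.0


def fish_average_cn(obs: FishObservation, observers: int = 2) -> float:
    """Average ERBB2 copies per cell from two-observer FISH counting.

    With the clinical protocol (2 observers, 50 cells each) this is the sum
    of the two observer totals divided by 100; the general form divides by
    ``observers * cells_per_observer``.
    """
    denom = observers * obs.cells_per_observer
    if denom <= 0:
        raise ValueError("observer/cell counts must be positive")
    return (obs.observer1_total + obs.observer2_total) / denom


def classify_cn(cn: float) -> Her2Class:
    """ASCO/CAP 2013 classification of an average ERBB2 copy number.

    negative if cn < 4; equivocal if 4 <= cn < 6; positive if cn >= 6.
    Classification always consumes the unrounded value; rounding is a
    reporting concern only.
    """
    if not math.isfinite(cn) or cn < 0:
        raise ValueError(f"copy number must be finite and non-negative, got {cn!r}")
    if cn < NEGATIVE_EQUIVOCAL_CUTOFF:
        return Her2Class.negative
    if cn < EQUIVOCAL_POSITIVE_CUTOFF:
        return Her2Class.equivocal
    return Her2Class.positive


def _round_half_up(value: float, places: int) -> float:
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def round_fish_cn(cn: float) -> float:
    """FISH copy numbers are reported to one decimal place (half-up)."""
    return _round_half_up(cn, 1)


def round_mip_cn(cn: float) -> float:
    """MIP/TuScan copy numbers are reported to two decimal places (half-up)."""
    return _round_half_up(cn, 2)
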