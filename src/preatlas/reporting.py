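"""Rounding and formatting conventions for reported summary numbers.

All percentages quoted in reports are integer, round-half-up; fold
enrichments are quoted to one decimal, round-half-up.  These helpers
exist so every module reports the same way.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def percent_int(numerator: float, denominator: float) -> int:
    """Integer percentage, round-half-up. 30/38 -> 79; 7/38 -> 18."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    pct = Decimal(numerator) / Decimal(denominator) * 100
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def round_half_up(x: float, decimals: int = 0) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fold_one_decimal(observed: float, reference: float) -> float:
    """Fold change to one decimal (30/38 over 7/38 -> 4.3)."""
    if reference == 0:
        return float("inf")
    return round_half_up(observed / reference, 1)


def format_fold(fold: float) -> str:
    """Render a fold enrichment the way reports quote it, e.g. '4.3-fold'."""
    return f"{fold:.1f}-fold"
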