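"""Rounding conventions shared across metric modules.

Printed percentages in the snapshot summary tables use round-half-away-
from-zero to one decimal; decade growth figures use an integer floor.
Both conventions are applied consistently everywhere so that recomputed
percentages are bit-identical to stored ones.
"""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round1_half_up", "percent"]


def round1_half_up(x: float) -> float:
    """Round to one decimal, halves away from zero."""
    sign = -1.0 if x < 0 else 1.0
    q = Decimal(repr(abs(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return sign * float(q)


def percent(part: int, total: int) -> float:
    """``100 * part / total`` rounded half-away-from-zero to one decimal.

    ``total`` must be >= 1 and ``0 <= part <= total``.
    """
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= part <= total:
        raise ValueError(f"part {part} outside [0, {total}]")
    return round1_half_up(100.0 * part / total)
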