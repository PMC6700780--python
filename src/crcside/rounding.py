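"""Half-up display rounding.

Report tables round half-up (0.575 -> 0.58, 88.57% -> 89%), which is
not what binary-float ``round`` does.  Ratios of integer counts are
rounded from exact decimal division; floats are rounded from their
shortest decimal representation.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal, localcontext
from fractions import Fraction


def round_half_up(value: float | Fraction, ndigits: int = 0) -> float:
    """Round to ``ndigits`` decimals with ties away from zero."""
    if isinstance(value, Fraction):
        return round_ratio(value.numerator, value.denominator, ndigits)
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def round_ratio(numerator: int, denominator: int, ndigits: int = 0) -> float:
    """Round the exact ratio of two integers half-up to ``ndigits``."""
    if denominator == 0:
        raise ZeroDivisionError("ratio with zero denominator")
    quantum = Decimal(1).scaleb(-ndigits)
    with localcontext() as ctx:
        ctx.prec = 50
        q = Decimal(numerator) / Decimal(denominator)
    return float(q.quantize(quantum, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int) -> int:
    """Integer percent, half-up, from two counts (62/99 -> 63)."""
    return int(round_ratio(100 * numerator, denominator, 0))
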