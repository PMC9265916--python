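"""Exact rational rate computation and report rounding.

Per-class prediction rates are reported half-up to one decimal; pooled
totals are truncated to two decimals.  Rates are formed as exact fractions
of integer counts before rounding so that e.g. 14/26 reproducibly prints
53.8 regardless of binary float representation.
"""

from __future__ import annotations

from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal
from fractions import Fraction

__all__ = ["round_half_up", "percent_1dp", "percent_2dp_trunc", "exact_fraction"]


def exact_fraction(x) -> Fraction:
    """Exact rational from a number, honouring its decimal repr for floats."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    return Fraction(str(x))


def round_half_up(x, ndigits: int = 1) -> float:
    """Round half away from zero at `ndigits` decimals, via exact decimals."""
    frac = exact_fraction(x)
    d = Decimal(frac.numerator) / Decimal(frac.denominator)
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def percent_1dp(numerator: int, denominator: int) -> float:
    """100·num/den, half-up to one decimal (per-class prediction rate)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(Fraction(100 * numerator, denominator), 1)


def percent_2dp_trunc(numerator: int, denominator: int) -> float:
    """100·num/den truncated to two decimals (pooled total rate)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    frac = Fraction(100 * numerator, denominator)
    d = Decimal(frac.numerator) / Decimal(frac.denominator)
    return float(d.quantize(Decimal("0.01"), rounding=ROUND_DOWN))
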