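"""Exact money arithmetic in Iranian Rials (IRR).

All cohort totals are integers of IRR; intermediate quantities involving
occurrence probabilities or currency conversion are exact ``Fraction``
values, rounded only at the edge of a report.  Binary floating point never
enters a total, so every printed figure is bit-reproducible.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Union

Rational = Union[int, Fraction]

__all__ = ["Rational", "as_rational", "round_half_away", "ValidationError"]


class ValidationError(ValueError):
    """An input violates a domain invariant (negative price, probability > 1, ...)."""


def as_rational(value: Union[int, float, str, Fraction]) -> Fraction:
    """Coerce a user-supplied number to an exact rational.

    Decimal strings (``"0.21"``), fraction strings (``"21/100"``) and ints
    are taken exactly.  Floats are interpreted through their shortest
    decimal repr — ``0.21`` means 21/100, not the nearest binary double —
    because config values are decimal by intent.
    """
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(repr(value))
    if isinstance(value, str):
        return Fraction(value)
    raise ValidationError(f"cannot interpret {value!r} as a rational number")


def round_half_away(x: Rational) -> int:
    """Round to the nearest integer, ties away from zero.

    This is the rounding used for every displayed IRR and USD figure
    (e.g. an expected cost of 36,682.5 IRR prints as 36,683).
    """
    x = Fraction(x)
    if x < 0:
        return -round_half_away(-x)
    whole, rem = divmod(x.numerator, x.denominator)
    if 2 * rem >= x.denominator:
        whole += 1
    return int(whole)
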