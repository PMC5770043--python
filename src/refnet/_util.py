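"""Small numeric helpers: exact half-up rounding on rational values.

Published rates in this domain are conventionally rounded half-up on the
exact quotient (16.532 -> 16.5, 23.608 -> 24), which binary floats get wrong
often enough to matter when reproducing printed tables; rates are therefore
carried as ``fractions.Fraction`` until the final rounding step.
"""

from __future__ import annotations

from fractions import Fraction
from math import floor


def round_half_up(value: Fraction | int | float, dp: int = 1) -> float:
    """Round ``value`` to ``dp`` decimal places, ties away from zero.

    Floats are converted through their shortest decimal representation so
    that e.g. 6.35 (stored as 6.3499...) still rounds to 6.4.
    """
    if not isinstance(value, Fraction):
        value = Fraction(str(value)) if isinstance(value, float) else Fraction(value)
    scale = Fraction(10) ** dp
    scaled = value * scale
    if scaled >= 0:
        q = floor(scaled + Fraction(1, 2))
    else:
        q = -floor(-scaled + Fraction(1, 2))
    return float(Fraction(q) / scale)


def percent(numerator: int, denominator: int, dp: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to ``dp`` decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(Fraction(100 * numerator, denominator), dp)


def ratio(numerator: int | Fraction, denominator: int | Fraction, dp: int = 2) -> float:
    """numerator / denominator rounded half-up to ``dp`` decimals."""
    num = Fraction(numerator)
    den = Fraction(denominator)
    if den == 0:
        raise ZeroDivisionError("ratio with zero denominator")
    return round_half_up(num / den, dp)
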