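"""Centralized rounding for reported percentages.

All cohort percentages in reports go through :func:`percentage` so that the
half-up, one-decimal convention is applied uniformly (e.g. 10/142 -> 7.0,
27/262 -> 10.3, 37/287 -> 12.9).  Using :class:`decimal.Decimal` on the exact
ratio avoids binary-float ties.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from typing import Optional


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round *value* half-up to *ndigits* decimals."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int, ndigits: int = 1) -> Optional[float]:
    """100 * numerator/denominator, half-up to *ndigits* decimals.

    Returns ``None`` (the "undefined" marker) when the denominator is zero;
    an empty subgroup has no percentage, not a zero one.
    """
    if denominator == 0:
        return None
    quantum = Decimal(1).scaleb(-ndigits)
    exact = Decimal(numerator) * 100 / Decimal(denominator)
    return float(exact.quantize(quantum, rounding=ROUND_HALF_UP))
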