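"""Small shared numeric helpers."""
from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals.

    Python's builtin ``round`` is banker's rounding; reported ratios here
    follow the half-away convention so that e.g. -4.785 -> -4.8.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half away from zero."""
    if denominator == 0:
        raise ValueError("percentage with zero denominator")
    return round_half_away(100.0 * numerator / denominator, decimals)
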