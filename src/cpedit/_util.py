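"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (half-up), not banker's rounding.

    Percentages in reports are rendered this way so that e.g. 4.345 -> 4.35.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """Half-up rounded percentage 100*numerator/denominator."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty total is undefined")
    return round_half_up(100.0 * numerator / denominator, ndigits)
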