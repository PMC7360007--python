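"""Small numeric helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (display convention for
    percentages), unlike banker's rounding used by :func:`round`."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(part: float, whole: float, ndigits: int = 0) -> float:
    """``part / whole`` as a percentage rounded half-away-from-zero."""
    if whole == 0:
        raise ZeroDivisionError("percentage of an empty total")
    return round_half_away(100.0 * part / whole, ndigits)
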