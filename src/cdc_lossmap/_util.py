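"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (half-up), the convention used for all
    reported percentages (e.g. 100*10/16 -> 62.5, 100*136/300 -> 45.3).

    Python's built-in ``round`` is banker's rounding, which would turn e.g.
    0.25 into 0.2; half-up matches how clinical frequencies are printed.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage ``100*count/total`` rounded half-up to ``ndigits``."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, ndigits)
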