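"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties going away from zero (the convention of reported EF tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def round_to_step(value: float, step: float) -> float:
    """Round ``value`` to the nearest multiple of ``step`` (ties away from zero)."""
    if step <= 0:
        raise ValueError("rounding step must be positive")
    n = Decimal(repr(float(value))) / Decimal(repr(float(step)))
    n = n.quantize(Decimal(1), rounding=ROUND_HALF_UP)
    return float(n * Decimal(repr(float(step))))
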