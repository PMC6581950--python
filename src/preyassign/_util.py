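"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero, matching printed-table
    conventions (banker's rounding would turn 0.125 into 0.12)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
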