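"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at the given decimal place.

    Printed tables in this domain use commercial (half-up) rounding, not
    banker's rounding, so ``round()`` is not a drop-in.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))
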