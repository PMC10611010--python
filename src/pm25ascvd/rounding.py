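"""Half-up decimal rounding used for published-table formatting.

numpy/python round half to even; risk tables in this literature round half
up (28.1435 -> 28.144), so table export goes through :func:`round_half_up`.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(value: float, decimals: int = 3) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))
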