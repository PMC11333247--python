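"""Round-half-up helpers matching the display convention of the published tables.

Python's built-in ``round`` is banker's rounding; the published tables round
half away from zero (0.20835 -> 0.2084 at 4 dp), so display paths go through
:func:`round_half_up` instead. Internal arithmetic is never rounded.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable


def round_half_up(value: float, decimals: int = 4) -> float:
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def round_vector(values: Iterable[float], decimals: int = 4) -> tuple[float, ...]:
    return tuple(round_half_up(v, decimals) for v in values)
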