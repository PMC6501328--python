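"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used in printed tables).

    Python's built-in ``round`` is banker's rounding; printed experimental
    tables almost universally use half-away-from-zero.
    """
    factor = 10.0**ndigits
    scaled = x * factor
    return math.copysign(math.floor(abs(scaled) + 0.5), scaled) / factor
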