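"""Decimal rounding matching published tables.

Printed tables round halves away from zero (0.2745 -> 0.275), whereas
Python's ``round`` is half-to-even on binary floats (0.2745 -> 0.274).
``round_half_up`` applies the half-away-from-zero convention with a tiny
fuzz so values a few ulps below an exact half boundary still round up.
"""

from __future__ import annotations

import math

_FUZZ = 1e-9


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round half away from zero at ``ndigits`` decimal places."""
    scaled = x * 10**ndigits
    if x >= 0:
        return math.floor(scaled + 0.5 + _FUZZ) / 10**ndigits
    return -math.floor(-scaled + 0.5 + _FUZZ) / 10**ndigits
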