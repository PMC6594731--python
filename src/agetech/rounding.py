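"""Display rounding helpers.

All pipeline arithmetic is carried at full floating-point precision;
values are rounded half-up (the spreadsheet convention, not Python's
banker's rounding) only when a table is written or displayed.
"""

from __future__ import annotations

import math


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round to `ndigits` decimals with ties away from zero for positives.

    ``round_half_up(0.5) == 1`` whereas builtin ``round(0.5) == 0``.
    """
    scale = 10.0**ndigits
    if x >= 0:
        r = math.floor(x * scale + 0.5) / scale
    else:
        r = math.ceil(x * scale - 0.5) / scale
    return r if ndigits > 0 else float(int(r))


def display_int(x: float) -> int:
    """Round half-up to a whole number for reporting person counts or AUD."""
    return int(round_half_up(x))
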