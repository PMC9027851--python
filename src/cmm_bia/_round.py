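"""Display rounding helpers.

All model arithmetic is carried out on unrounded doubles; rounding is a
presentation step only. The display convention is round-half-up (22.5 -> 23),
not Python's built-in banker's rounding.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` half-up to ``ndigits`` decimal places.

    Negative values round toward larger magnitude at the .5 boundary of the
    absolute value (-2.5 -> -3), which is the convention used for displaying
    signed currency amounts.
    """
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


def display_int(x: float) -> int:
    """Half-up rounding to a whole number, returned as int (headcounts, EUR)."""
    return int(round_half_up(x, 0))
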