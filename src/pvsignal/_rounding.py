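"""Decimal rounding helpers.

Published safety tables are typeset with half-up rounding, but some printed
percentages are only reproducible by truncation toward zero, so both modes
are exposed and every display-rounding call site takes a mode argument.
Internal statistics are never rounded.
"""

from __future__ import annotations

from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

ROUNDING_MODES = ("half_up", "truncate")


def round_display(x: float, ndigits: int, mode: str = "half_up") -> float:
    """Round ``x`` to ``ndigits`` decimals for display.

    mode="half_up" rounds .5 away from zero (the convention of printed
    clinical tables, unlike Python's bankers' rounding); mode="truncate"
    drops digits toward zero.
    """
    if mode not in ROUNDING_MODES:
        raise ValueError(f"unknown rounding mode {mode!r}; expected one of {ROUNDING_MODES}")
    q = Decimal(1).scaleb(-ndigits)
    rounding = ROUND_HALF_UP if mode == "half_up" else ROUND_DOWN
    return float(Decimal(repr(x)).quantize(q, rounding=rounding))
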