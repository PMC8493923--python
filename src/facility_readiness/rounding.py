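"""Reporting-grade rounding.

Published tables use round-half-to-even: 34/160 prints as 21.2% and
50/160 as 31.2% (both .x25 cases round down to the even digit). Plain
binary-float rounding gets the common cases right, but going through
:class:`decimal.Decimal` keeps count/total percentages exact.
"""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, Decimal


def percent(count: int, total: int, decimals: int = 1) -> float:
    """count/total as a percentage, rounded half-to-even to `decimals`."""
    if total <= 0:
        raise ValueError("total must be positive")
    exact = (Decimal(count) * 100) / Decimal(total)
    quantum = Decimal(1).scaleb(-decimals)
    return float(exact.quantize(quantum, rounding=ROUND_HALF_EVEN))


def round_half_even(value: float, decimals: int = 1) -> float:
    """Round a float half-to-even at `decimals` via its shortest repr."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_EVEN))
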