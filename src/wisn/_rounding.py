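"""Half-up rounding helpers.

Python's builtin ``round`` is banker's rounding; staffing arithmetic needs
the commercial half-up rule (0.5 rounds away from zero for nonnegative
inputs).  Going through ``Decimal(repr(x))`` applies the rule to the number
as printed, avoiding binary-representation artifacts like 2.675 -> 2.67.
"""

from __future__ import annotations

from decimal import ROUND_CEILING, ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def ceil_decimal(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal(1), rounding=ROUND_CEILING))
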