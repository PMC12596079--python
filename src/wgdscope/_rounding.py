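"""Centralized half-up rounding.

All human-facing percentages and ratios in the package go through
:func:`round_half_up` so that rendered numbers never depend on the
platform's banker's-rounding behaviour.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round ``x`` to ``decimals`` places, ties away from zero toward +inf.

    Uses decimal arithmetic on the repr of ``x`` so that values like 2.675
    round on their printed value, not their binary expansion.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
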