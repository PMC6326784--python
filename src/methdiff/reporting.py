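"""Shared rounding/percentage helpers for reported fractions.

Headline fractions are reported in the "~88%" style: percentages round
half-up to the requested number of decimals while the exact value is kept
alongside wherever it matters.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round with ties away from the floor (0.5 → 1), unlike banker's rounding."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def fraction_percent(numerator: int, denominator: int,
                     decimals: int = 0) -> float:
    """100·numerator/denominator, rounded half-up to ``decimals``."""
    if denominator == 0:
        raise ZeroDivisionError("fraction_percent: zero denominator")
    return round_half_up(100.0 * numerator / denominator, decimals)
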