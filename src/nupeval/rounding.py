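"""Half-away-from-zero rounding used for every reported percentage.

Python's built-in ``round`` is banker's rounding (half-to-even), which turns
55.555... into 55.6 but 62.25 into 62.2; the score tables in this package use
commercial rounding instead, so ties always move away from zero.
"""

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "percent_of_max"]


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round ``value`` to ``decimals`` places, ties away from zero.

    >>> round_half_up(55.555555, 1)
    55.6
    >>> round_half_up(0.25, 1)
    0.3
    """
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    quantum = Decimal(1).scaleb(-decimals)
    # Decimal(repr(...)) avoids binary-float artifacts like 0.1 -> 0.1000...55
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def percent_of_max(total: float, maximum: float, decimals: int = 1) -> float:
    """A score total expressed as a percentage of its maximum, rounded."""
    if maximum <= 0:
        raise ValueError("maximum must be positive")
    return round_half_up(100.0 * total / maximum, decimals)
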