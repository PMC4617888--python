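"""Unit conventions.

All distribution mathematics runs on the daily death probability ``p``
(per person-day).  Every external interface reports the rate
``r = 10,000 * p`` in deaths/10,000/day, the scale used throughout
humanitarian practice (Sphere thresholds, SMART surveys).
"""

import decimal

#: multiplier between daily death probability and the reported rate
RATE_SCALE = 10_000.0

#: unit string attached to every reported rate
RATE_UNIT = "deaths/10,000/day"


def rate_to_prob(rate: float) -> float:
    """Convert a rate in deaths/10,000/day to a daily probability."""
    return rate / RATE_SCALE


def prob_to_rate(p: float) -> float:
    """Convert a daily probability to deaths/10,000/day."""
    return p * RATE_SCALE


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (the convention of printed Sphere tables).

    Python's built-in ``round`` is banker's rounding; printed humanitarian
    tables round .5 away from zero, which matters for threshold doubling
    (e.g. 2 x 0.15 = 0.30, 2 x 0.27 = 0.54 -> 0.5).
    """
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))
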