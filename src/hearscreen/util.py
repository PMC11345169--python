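"""Small shared helpers: half-up rounding and validation errors."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


class InvalidParameterError(ValueError):
    """A model input violates its domain (negative cost, probability outside [0,1], ...)."""


class UndefinedMetricError(ZeroDivisionError):
    """A ratio metric was requested with a zero denominator (e.g. PPV with no referrals)."""


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (commercial rounding), as used for reported INR values.

    Python's built-in ``round`` is banker's rounding; reported currency values
    here follow half-up convention (96.5 -> 97).
    """
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)
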