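"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


class ValidationError(ValueError):
    """Raised when input data violate a schema or operation precondition."""


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as the study's tables do.

    Python's built-in ``round`` uses banker's rounding, which would turn
    e.g. 0.25% into 0.2% where the published tables print 0.3%.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def percent(value: float, ndigits: int = 1) -> float:
    """Proportion -> percent, rounded half-up to ``ndigits`` decimals."""
    return round_half_up(100.0 * value, ndigits)
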