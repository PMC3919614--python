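"""Small numeric helpers shared across modules."""

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (half-up), as in the reported tables.

    Python's builtin ``round`` is banker's rounding; reported percentages such
    as 80.3% and allele fractions such as 1.00 use conventional half-up.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage ``100 * numerator / denominator`` rounded half-up."""
    if denominator == 0:
        raise ZeroDivisionError("percentage undefined for zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)
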