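"""Small shared helpers."""

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (half-up), e.g. 0.885 -> 0.89.

    Python's builtin ``round`` uses banker's rounding; reported conservation
    values use the conventional half-up rule instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
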