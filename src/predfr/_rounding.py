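"""Half-up decimal rounding for report output.

Python's builtin ``round`` uses banker's rounding; published ecology tables
round half away from zero, so report layers go through this helper. Internal
computation always keeps full precision.
"""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` half-up to ``ndigits`` decimal places.

    >>> round_half_up(0.125, 2)
    0.13
    >>> round_half_up(41.6667, 2)
    41.67
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
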