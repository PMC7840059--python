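"""Half-up decimal rounding, the convention used for all reported percentages."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` half away from zero at ``ndigits`` decimals.

    Python's builtin ``round`` is banker's rounding; clinical reports round
    half up (2.045 -> 2.05).  Goes through ``Decimal(str(x))`` so the value
    rounded is the shortest decimal representation of ``x``, not its binary
    expansion.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))
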