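"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (report-style rounding).

    Python's builtin ``round`` is banker's rounding; clinical tables
    conventionally round 0.5 up in magnitude (1.275 -> 1.28 at 2 dp).
    Goes through ``repr`` so that doubles that *print* as a tie (e.g.
    ``5712/4480 == 1.275``) are treated as one.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
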