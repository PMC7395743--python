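"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero (spreadsheet convention, not banker's).

    Published survey tables round this way, so reproducing printed
    percentages requires it rather than Python's built-in round().
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
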