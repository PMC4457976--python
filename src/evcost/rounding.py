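"""Half-up decimal rounding.

Python's built-in ``round`` is banker's rounding; financial reporting in this
package rounds halves away from zero (4,087,310.5 USD -> 4,087,311 USD).
All helpers go through :class:`decimal.Decimal` constructed from the shortest
repr of the float, so values that are exact in decimal (prices, printed table
cells) round the way they read, not the way their binary image happens to fall.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "to_decimal"]


def to_decimal(x: float | int | str | Decimal) -> Decimal:
    """Exact decimal image of ``x`` (via repr for floats)."""
    if isinstance(x, Decimal):
        return x
    if isinstance(x, int):
        return Decimal(x)
    return Decimal(repr(float(x)) if isinstance(x, float) else x)


def round_half_up(x: float | int | Decimal, decimals: int = 0) -> float | int:
    """Round ``x`` to ``decimals`` places, halves away from zero.

    Returns an ``int`` when ``decimals <= 0``, else a ``float``.
    """
    q = Decimal(1).scaleb(-decimals)
    d = to_decimal(x).quantize(q, rounding=ROUND_HALF_UP)
    return int(d) if decimals <= 0 else float(d)
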