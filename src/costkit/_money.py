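"""Decimal money helpers.

Ledger prices span five orders of magnitude (0.15 INR phone-bill shares up to
lakh-scale workshop costs), so money is held as exact :class:`decimal.Decimal`
and only rounded at report boundaries. Reported integer INR figures use
half-up rounding (1206.5 -> 1207), the convention that reproduces every
printed table cell this package is tested against.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

TWO_DP = Decimal("0.01")


def D(x) -> Decimal:
    """Coerce to Decimal. Floats go through repr() so the shortest
    round-tripping decimal literal is used, not the raw binary expansion."""
    if isinstance(x, Decimal):
        return x
    if isinstance(x, float):
        return Decimal(repr(x))
    return Decimal(x)


def parse_money(text: str) -> Decimal:
    """Parse a money string, accepting Indian digit grouping ("4,91,040")
    as well as Western grouping; grouping is never emitted on output."""
    cleaned = text.strip().replace(",", "").replace(" ", "")
    if cleaned in ("", "-"):
        raise ValueError(f"empty money field: {text!r}")
    return Decimal(cleaned)


def fmt_money(x: Decimal) -> str:
    """Serialize money with exactly two decimal places."""
    return str(D(x).quantize(TWO_DP, rounding=ROUND_HALF_UP))


def fmt_fraction(x: Decimal) -> str:
    """Serialize a fraction at 2 dp when exact at that precision (0.5 ->
    "0.50"), otherwise at full precision so round trips are lossless."""
    x = D(x)
    q = x.quantize(TWO_DP)
    return str(q) if q == x else str(x)


def round_half_up(x, ndigits: int = 0):
    """Half-up rounding (unlike Python's banker's rounding)."""
    quantum = Decimal(1).scaleb(-ndigits)
    q = D(x).quantize(quantum, rounding=ROUND_HALF_UP)
    return int(q) if ndigits == 0 else q


def pct(part: Decimal, whole: Decimal) -> Decimal:
    """part/whole as a percentage rounded half-up to 2 dp; 0 if whole is 0."""
    if whole == 0:
        return Decimal("0.00")
    return (D(part) / D(whole) * 100).quantize(TWO_DP, rounding=ROUND_HALF_UP)
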