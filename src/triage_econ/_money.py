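"""Exact currency arithmetic.

All monetary quantities are ``decimal.Decimal`` values carried at cent
precision.  Sums and products of cent-exact inputs stay exact; division
(depreciation and capacity allocation) is rounded half-up to cents only when
a per-examination figure is materialised, so cost chains such as
271 x 65.35 = 17,709.85 reproduce to the cent.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

CENT = Decimal("0.01")


def money(value: "Decimal | int | float | str") -> Decimal:
    """Coerce *value* to a cent-quantised Decimal.

    Accepts plain numbers, strings with a decimal point, and strings in the
    continental-European print convention with a decimal comma and optional
    thousands separators ("1.242.000" or "41,55").
    """
    if isinstance(value, Decimal):
        return value.quantize(CENT, rounding=ROUND_HALF_UP)
    if isinstance(value, str):
        value = _normalise_numeric_string(value)
        return Decimal(value).quantize(CENT, rounding=ROUND_HALF_UP)
    if isinstance(value, float):
        # repr round-trip avoids binary-float dust (0.1 -> "0.1")
        return Decimal(repr(value)).quantize(CENT, rounding=ROUND_HALF_UP)
    return Decimal(value).quantize(CENT, rounding=ROUND_HALF_UP)


def _normalise_numeric_string(s: str) -> str:
    s = s.strip().replace("€", "").replace(" ", "")
    if "," in s and "." in s:
        # whichever separator comes last is the decimal mark
        if s.rfind(",") > s.rfind("."):
            s = s.replace(".", "").replace(",", ".")
        else:
            s = s.replace(",", "")
    elif "," in s:
        # a single comma is a decimal mark; multiple commas group thousands
        if s.count(",") == 1:
            s = s.replace(",", ".")
        else:
            s = s.replace(",", "")
    elif s.count(".") > 1:
        # multiple points can only be thousands separators
        s = s.replace(".", "")
    return s


def round_cents(value: Decimal) -> Decimal:
    """Round half-up to cents (report boundary)."""
    return value.quantize(CENT, rounding=ROUND_HALF_UP)
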