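"""Fixed-point euro arithmetic.

All monetary quantities in the package are :class:`decimal.Decimal` values
quantized to cents. Rounding is commercial half-up, applied once per printed
quantity (a per-diem product is rounded after the single multiplication, not
per day).
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

CENT = Decimal("0.01")


def money(value: str | int | float | Decimal) -> Decimal:
    """Coerce ``value`` to a cent-quantized Decimal (half-up).

    Floats are routed through ``str`` so that e.g. ``money(255.26)`` is exact.
    """
    if isinstance(value, float):
        value = str(value)
    return Decimal(value).quantize(CENT, rounding=ROUND_HALF_UP)


def parse_money(text: str) -> Decimal:
    """Parse a euro amount, accepting German formatting.

    ``"11.116,78"`` and ``"11116.78"`` both parse to ``Decimal('11116.78')``.
    A comma is treated as the decimal separator; dots to its left are
    thousands separators.
    """
    s = text.strip().replace("€", "").replace(" ", "")
    if "," in s:
        s = s.replace(".", "").replace(",", ".")
    return money(s)


def fmt_eur(value: Decimal) -> str:
    """Render a Decimal with two decimal places (dot decimal, no grouping)."""
    return f"{money(value):.2f}"
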