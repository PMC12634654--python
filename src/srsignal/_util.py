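"""Small shared helpers: printed-precision rounding, name normalization, dates."""

from __future__ import annotations

import datetime as _dt
import re
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

_WS = re.compile(r"\s+")


def round_half_up(value: float | Fraction, ndigits: int) -> float:
    """Round with ties away from zero, matching hand-tabulated report values.

    Python's built-in ``round`` is banker's rounding; published baseline
    tables use half-up at the printed precision, so we go through Decimal.
    """
    if isinstance(value, Fraction):
        d = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        d = Decimal(repr(float(value)))
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def normalize_name(name: str) -> str:
    """Trim, collapse internal whitespace, uppercase. Used for drug and PT matching."""
    return _WS.sub(" ", name.strip()).upper()


def yyyymmdd(d: _dt.date) -> str:
    return f"{d.year:04d}{d.month:02d}{d.day:02d}"


def quarter_label(d: _dt.date) -> str:
    """Two-digit-year quarter tag, e.g. 2024-09-30 -> '24Q3'."""
    return f"{d.year % 100:02d}Q{(d.month - 1) // 3 + 1}"
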