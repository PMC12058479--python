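"""Small shared helpers: FAERS date parsing and presentation rounding."""

from __future__ import annotations

import datetime as _dt
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd


def parse_faers_date(raw: str | None) -> _dt.date | None:
    """Parse a FAERS date string (YYYYMMDD, YYYYMM or YYYY).

    Partial dates are resolved deterministically: YYYYMM becomes the first
    day of the month and a bare YYYY becomes July 1 of that year (the
    median-unbiased choice within the year).  Anything unparseable returns
    ``None``.
    """
    if raw is None:
        return None
    s = str(raw).strip()
    if not s or not s.isdigit():
        return None
    try:
        if len(s) == 8:
            return _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
        if len(s) == 6:
            return _dt.date(int(s[:4]), int(s[4:6]), 1)
        if len(s) == 4:
            return _dt.date(int(s), 7, 1)
    except ValueError:
        return None
    return None


def format_faers_date(value) -> str:
    """Inverse of :func:`parse_faers_date` for complete dates; NaT -> ''."""
    if value is None or pd.isna(value):
        return ""
    ts = pd.Timestamp(value)
    return f"{ts.year:04d}{ts.month:02d}{ts.day:02d}"


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at *ndigits* decimals (presentation rule)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: float, total: float, ndigits: int = 2) -> float:
    """100 * count / total, rounded half-up to *ndigits* decimals."""
    if total == 0:
        raise ValueError("percentage undefined for total == 0")
    return round_half_up(100.0 * count / total, ndigits)
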