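"""Partial-date handling for spontaneous-report data.

FAERS dates are ``YYYYMMDD`` integers that are legitimately partial: a
reporter may know only the month (``YYYYMM``) or year (``YYYY``) of an
event.  Dates are therefore kept verbatim together with a precision tag
instead of being coerced to a calendar date; each downstream operation
decides for itself whether a partial date is usable.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Optional

__all__ = ["PartialDate", "parse_partial_date"]

#: precision levels, most precise first
DAY, MONTH, YEAR = "day", "month", "year"


@dataclass(frozen=True)
class PartialDate:
    """A calendar date known to day, month or year precision."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    @property
    def precision(self) -> str:
        if self.day is not None:
            return DAY
        if self.month is not None:
            return MONTH
        return YEAR

    def sort_key(self) -> int:
        """YYYYMMDD integer with unknown month/day padded with 01 (lowest).

        A fully dated value therefore outranks a partial one of the same
        year, which makes duplicate resolution deterministic.
        """
        return self.year * 10000 + (self.month or 1) * 100 + (self.day or 1)

    def to_date(self) -> _dt.date:
        """Convert to :class:`datetime.date`; requires day precision."""
        if self.precision != DAY:
            raise ValueError(f"date {self} lacks day precision")
        return _dt.date(self.year, self.month, self.day)

    def __str__(self) -> str:  # FAERS dialect round-trip
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"


def parse_partial_date(raw) -> Optional[PartialDate]:
    """Parse a FAERS date token (``YYYYMMDD``/``YYYYMM``/``YYYY``).

    Returns ``None`` for missing or unparseable input — an unparseable
    date never rejects the enclosing record, it just loses the field.
    """
    if raw is None:
        return None
    s = str(raw).strip()
    if not s or s.lower() in ("nan", "none"):
        return None
    if not s.isdigit():
        return None
    try:
        if len(s) == 8:
            pd_ = PartialDate(int(s[:4]), int(s[4:6]), int(s[6:8]))
            pd_.to_date()  # validate calendar
            return pd_
        if len(s) == 6:
            y, m = int(s[:4]), int(s[4:6])
            if not 1 <= m <= 12:
                return None
            return PartialDate(y, m)
        if len(s) == 4:
            return PartialDate(int(s))
    except ValueError:
        return None
    return None
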