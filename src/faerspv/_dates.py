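"""Partial-date handling for spontaneous-report tables.

FAERS dates are plain digit strings of length 8 (``YYYYMMDD``), 6 (``YYYYMM``)
or 4 (``YYYY``); anything else — empty fields, oddly sized strings, impossible
calendar dates — is treated as missing.  Every raw value maps to a tagged
:class:`PartialDate`, so downstream rules ("day precision required",
"missing sorts lowest") can be expressed without exceptions.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)

DAY = "day"
MONTH = "month"
YEAR = "year"
MISSING = "missing"


@dataclass(frozen=True)
class PartialDate:
    """A calendar date known to day, month or year precision, or missing."""

    year: int | None
    month: int | None
    day: int | None
    precision: str  # one of DAY, MONTH, YEAR, MISSING

    @property
    def is_day(self) -> bool:
        return self.precision == DAY

    @property
    def is_missing(self) -> bool:
        return self.precision == MISSING

    def to_date(self) -> dt.date | None:
        """Full calendar date, only available at day precision."""
        if self.precision != DAY:
            return None
        return dt.date(self.year, self.month, self.day)

    def sort_key(self) -> tuple[int, int, int, int]:
        """Lexicographic key where missing ranks below any present date.

        Month/year precision fill unknown components with 0, so a partially
        known date ranks below any fully known date in the same period.
        """
        if self.precision == MISSING:
            return (0, 0, 0, 0)
        return (1, self.year, self.month or 0, self.day or 0)

    def __str__(self) -> str:
        if self.precision == MISSING:
            return ""
        if self.precision == YEAR:
            return f"{self.year:04d}"
        if self.precision == MONTH:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}{self.month:02d}{self.day:02d}"


MISSING_DATE = PartialDate(None, None, None, MISSING)


def parse_partial_date(raw: object) -> PartialDate:
    """Parse a FAERS-style digit string into a :class:`PartialDate`.

    8 digits give day precision, 6 month, 4 year; empty or malformed input
    (including impossible calendar dates such as month 13) maps to missing —
    never an exception.
    """
    if raw is None:
        return MISSING_DATE
    s = str(raw).strip()
    if s.endswith(".0"):  # tolerate float round-trips through CSV readers
        s = s[:-2]
    if not s or s.lower() in {"nan", "none"}:
        return MISSING_DATE
    if not s.isdigit() or len(s) not in (4, 6, 8):
        logger.debug("unparseable date %r treated as missing", raw)
        return MISSING_DATE
    year = int(s[:4])
    if len(s) == 4:
        return PartialDate(year, None, None, YEAR)
    month = int(s[4:6])
    if not 1 <= month <= 12:
        logger.warning("impossible date %r treated as missing", raw)
        return MISSING_DATE
    if len(s) == 6:
        return PartialDate(year, month, None, MONTH)
    day = int(s[6:8])
    try:
        dt.date(year, month, day)
    except ValueError:
        logger.warning("impossible date %r treated as missing", raw)
        return MISSING_DATE
    return PartialDate(year, month, day, DAY)
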