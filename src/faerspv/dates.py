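"""Partial calendar dates as they occur in FAERS date fields.

FAERS date columns (FDA_DT, EVENT_DT, START_DT, END_DT) hold 4, 6 or 8
digit strings: a bare year, a year-month, or a full date. Day-level
arithmetic (e.g. time to onset) is only defined at full precision, but
partially specified dates still have to order reports for deduplication,
so the comparison key treats missing components as zero — an absent
month/day sorts before any specified one.
"""

from __future__ import annotations

import calendar
import datetime
import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)

MIN_YEAR = 1900
MAX_YEAR = 2100


@dataclass(frozen=True)
class PartialDate:
    """A calendar date with year, optional month, optional day."""

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if not (MIN_YEAR <= self.year <= MAX_YEAR):
            raise ValueError(f"year {self.year} outside {MIN_YEAR}..{MAX_YEAR}")
        if self.month is None:
            if self.day is not None:
                raise ValueError("day given without month")
        elif not (1 <= self.month <= 12):
            raise ValueError(f"month {self.month} outside 1..12")
        elif self.day is not None:
            last = calendar.monthrange(self.year, self.month)[1]
            if not (1 <= self.day <= last):
                raise ValueError(f"day {self.day} invalid for {self.year}-{self.month}")

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"

    def sort_key(self) -> tuple[int, int, int]:
        """Total-order key; missing components sort earliest."""
        return (self.year, self.month or 0, self.day or 0)

    def to_date(self) -> datetime.date:
        if self.precision != "day":
            raise ValueError(f"{self} has no day precision")
        return datetime.date(self.year, self.month, self.day)

    def format(self) -> str:
        """Canonical FAERS digit string (YYYY, YYYYMM or YYYYMMDD)."""
        out = f"{self.year:04d}"
        if self.month is not None:
            out += f"{self.month:02d}"
            if self.day is not None:
                out += f"{self.day:02d}"
        return out

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.format()


def parse_partial_date(raw: str | None) -> PartialDate | None:
    """Parse a FAERS date string; anything unparseable is missing.

    Total function: empty/garbage input yields ``None`` with a logged
    warning, never an exception.
    """
    if raw is None:
        return None
    raw = raw.strip()
    if not raw:
        return None
    if not raw.isdigit() or len(raw) not in (4, 6, 8):
        logger.warning("unparseable date %r treated as missing", raw)
        return None
    year = int(raw[:4])
    month = int(raw[4:6]) if len(raw) >= 6 else None
    day = int(raw[6:8]) if len(raw) == 8 else None
    try:
        return PartialDate(year, month, day)
    except ValueError:
        logger.warning("invalid calendar date %r treated as missing", raw)
        return None


def days_between(start: PartialDate, end: PartialDate) -> int:
    """Whole days from start to end; both must have day precision."""
    return (end.to_date() - start.to_date()).days
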