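"""Calendar helpers.

Dates are carried internally as integer days since 1970-01-01 (the numpy
datetime64[D] epoch); person-years use 365.25 days. Calendar months are real
calendar months, used for look schedules and for the seasonal terms.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

DAYS_PER_YEAR = 365.25

_EPOCH = np.datetime64("1970-01-01", "D")


def to_day(date) -> int:
    """Convert an ISO string / date / datetime64 to integer days since 1970-01-01."""
    if isinstance(date, (int, np.integer)):
        return int(date)
    if isinstance(date, _dt.date):
        date = date.isoformat()
    return int((np.datetime64(date, "D") - _EPOCH).astype(int))


def to_date(day: int) -> np.datetime64:
    """Inverse of :func:`to_day`."""
    return _EPOCH + np.timedelta64(int(day), "D")


def to_iso(day) -> str:
    return str(to_date(int(day)))


def month_ends(start_day: int, end_day: int) -> np.ndarray:
    """Integer days of the last day of each calendar month overlapping [start, end].

    The final entry is clipped to ``end_day``, so the sequence always ends on
    ``end_day`` itself (a partial final month counts as a look).
    """
    start = to_date(start_day).astype("datetime64[M]")
    end = to_date(end_day).astype("datetime64[M]")
    months = np.arange(start, end + 1) + 1  # first day of next month
    ends = months.astype("datetime64[D]") - 1
    days = (ends - _EPOCH).astype(int)
    days[-1] = min(days[-1], end_day)
    return np.minimum(days, end_day)


def month_index(days: np.ndarray, origin_day: int) -> np.ndarray:
    """0-based calendar-month index of each day relative to the origin's month."""
    d = (_EPOCH + np.asarray(days, dtype="timedelta64[D]")).astype("datetime64[M]")
    o = to_date(origin_day).astype("datetime64[M]")
    return (d - o).astype(int)


def day_of_year(days: np.ndarray) -> np.ndarray:
    """Fractional position within the year, in days (0..365)."""
    d = _EPOCH + np.asarray(days, dtype="timedelta64[D]")
    year_start = d.astype("datetime64[Y]").astype("datetime64[D]")
    return (d - year_start).astype(int)


def age_years(days, birth_days) -> np.ndarray:
    return (np.asarray(days, dtype=float) - np.asarray(birth_days, dtype=float)) / DAYS_PER_YEAR
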