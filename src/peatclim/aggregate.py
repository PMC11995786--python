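"""Daily-to-sub-annual aggregation on a 365-day calendar.

The whole pipeline operates on N sub-annual intervals per year: N = 12
calendar months, or N = 52 weeks built as fifty-one 7-day weeks plus one
final 8-day week so that interval day counts always sum to 365 and
precipitation mass is conserved exactly.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .types import DAYS_PER_YEAR, DailySeries, ShapeError, SubAnnualSeries, ValidationError

MONTH_DAY_COUNTS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)


@dataclasses.dataclass(frozen=True)
class IntervalCalendar:
    """Partition of the 365-day year into N intervals.

    Attributes
    ----------
    day_counts : ndarray of int, shape (N,)
        Days per interval; sums to 365.
    starts : ndarray of int, shape (N,)
        1-based Julian day each interval begins on.
    median_julian : ndarray of int, shape (N,)
        Julian day of each interval's middle day (lower middle for
        even-length intervals); used as the interval's time coordinate for
        solar declination.
    interval_of_day : ndarray of int, shape (365,)
        0-based interval index for each day of year.
    """

    day_counts: np.ndarray
    starts: np.ndarray
    median_julian: np.ndarray
    interval_of_day: np.ndarray

    @property
    def n_intervals(self) -> int:
        return self.day_counts.size


def make_calendar(n_intervals: int) -> IntervalCalendar:
    """Build the monthly (N=12) or weekly (N=52) interval calendar."""
    if n_intervals == 12:
        counts = np.asarray(MONTH_DAY_COUNTS, dtype=int)
    elif n_intervals == 52:
        counts = np.full(52, 7, dtype=int)
        counts[-1] = 8
    else:
        raise ValidationError(f"unsupported interval count {n_intervals}; expected 12 or 52")
    starts = np.concatenate(([1], 1 + np.cumsum(counts)[:-1]))
    median = starts + (counts - 1) // 2
    interval_of_day = np.repeat(np.arange(counts.size), counts)
    cal = IntervalCalendar(
        day_counts=counts, starts=starts, median_julian=median, interval_of_day=interval_of_day
    )
    assert cal.day_counts.sum() == DAYS_PER_YEAR
    return cal


def daily_mean_temp(tmin_c, tmax_c):
    """Mean daily temperature as the midpoint of the daily extremes."""
    tmin_c = np.asarray(tmin_c, dtype=float)
    tmax_c = np.asarray(tmax_c, dtype=float)
    if np.any(tmin_c > tmax_c):
        raise ValidationError("tmin > tmax")
    out = 0.5 * (tmin_c + tmax_c)
    return out if out.ndim else float(out)


def aggregate_daily(daily: DailySeries, calendar: IntervalCalendar):
    """Aggregate a whole-year daily series to (precip, temp) sub-annual series.

    Precipitation is summed within each interval (conserving the annual
    total exactly); temperature is the arithmetic mean of the daily mean
    temperatures. The series must start on Jan 1 of the 365-day calendar and
    contain a whole number of years.
    """
    if daily.start_doy != 1:
        raise ValidationError(
            f"daily series must start on day 1 of the 365-day year, starts on day {daily.start_doy}"
        )
    if daily.n_days % DAYS_PER_YEAR != 0:
        raise ValidationError(
            f"daily series length {daily.n_days} is not a whole number of 365-day years"
        )
    n_years = daily.n_years
    idx = calendar.starts - 1  # reduceat offsets
    precip = np.add.reduceat(daily.precip_mm.reshape(n_years, DAYS_PER_YEAR), idx, axis=1)
    tsum = np.add.reduceat(daily.tmean_c.reshape(n_years, DAYS_PER_YEAR), idx, axis=1)
    temp = tsum / calendar.day_counts
    epoch = daily.start_date.year
    return (
        SubAnnualSeries(precip, kind="precip_total_mm", epoch=epoch),
        SubAnnualSeries(temp, kind="temp_mean_c", epoch=epoch),
    )
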