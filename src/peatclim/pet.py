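"""Potential evapotranspiration via the modified Thornthwaite method.

The classic Thornthwaite formulation is monthly; here the annual heat index
rescales each interval's contribution by 12/N so the same equations apply to
weekly (N = 52) series, and the raw interval PET — defined for a reference
30-day interval at 12 hours of daylight — is scaled by the actual daylight
hours (from latitude and solar declination at the interval's median Julian
date) and the interval's day count.

Temperatures at or below 0 degC contribute nothing to the heat index and
yield zero PET, the standard Thornthwaite convention for freezing intervals.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .aggregate import IntervalCalendar
from .types import ShapeError, SiteMeta, SubAnnualSeries

#: Thornthwaite heat-index exponent applied to (t/5).
HEAT_INDEX_POWER = 1.514
#: Cubic polynomial coefficients of the PET exponent a(I), constant first.
EXPONENT_COEFFS = (0.49239, 1792e-5, -771e-7, 675e-9)


def heat_index(temps, n_intervals: int | None = None) -> float | np.ndarray:
    """Annual heat index I from one or more years of interval temperatures.

    ``I = sum_n (max(t_n, 0)/5)**1.514 * (12/N)``; the 12/N factor treats
    any interval resolution as month-equivalent, so a year of constant
    temperature gives the same I for N = 12 and N = 52.

    Parameters
    ----------
    temps : array-like, shape (N,) or (Y, N)
        Interval mean temperatures (degC) for one year or a stack of years.
    n_intervals : int, optional
        Intervals per year; defaults to the trailing axis length.
    """
    t = np.atleast_2d(np.asarray(temps, dtype=float))
    n = n_intervals if n_intervals is not None else t.shape[1]
    if t.shape[1] != n:
        raise ShapeError(f"expected {n} intervals per year, got {t.shape[1]}")
    terms = (np.maximum(t, 0.0) / 5.0) ** HEAT_INDEX_POWER
    out = terms.sum(axis=1) * (12.0 / n)
    return out if np.asarray(temps).ndim == 2 else float(out[0])


def exponent_a(heat_idx) -> float | np.ndarray:
    """Thornthwaite exponent a as a cubic polynomial in the heat index."""
    i = np.asarray(heat_idx, dtype=float)
    c0, c1, c2, c3 = EXPONENT_COEFFS
    out = c0 + i * (c1 + i * (c2 + i * c3))
    return out if out.ndim else float(out)


def pet_unscaled(temp_c, heat_idx, a) -> float | np.ndarray:
    """Reference-interval PET (mm for 30 days at 12 h daylight).

    Zero at or below freezing; otherwise ``16 * (10 t / I) ** a``.
    """
    t = np.asarray(temp_c, dtype=float)
    i = np.asarray(heat_idx, dtype=float)
    a = np.asarray(a, dtype=float)
    if np.any((i <= 0) & (t > 0)):
        raise ValueError("heat index must be positive for a year containing t > 0")
    safe_i = np.where(i > 0, i, 1.0)
    out = np.where(t > 0, 16.0 * (10.0 * np.maximum(t, 0.0) / safe_i) ** a, 0.0)
    return out if out.ndim else float(out)


def solar_declination(median_julian) -> float | np.ndarray:
    """Solar declination (degrees) at a Julian date, degree-form approximation
    ``23.45 * sin((J - 81) * 360/365 deg)``."""
    j = np.asarray(median_julian, dtype=float)
    out = 23.45 * np.sin(np.deg2rad((j - 81.0) * 360.0 / 365.0))
    return out if out.ndim else float(out)


def day_length(lat, declination) -> float | np.ndarray:
    """Daylight hours from latitude and solar declination (both degrees).

    ``L = (24/pi) * arccos(-tan(lat) tan(delta))`` with the arccos argument
    clamped to [-1, 1]: -1 gives a 24 h polar day, +1 a 0 h polar night.
    """
    lat_r = np.deg2rad(np.asarray(lat, dtype=float))
    dec_r = np.deg2rad(np.asarray(declination, dtype=float))
    arg = np.clip(-np.tan(lat_r) * np.tan(dec_r), -1.0, 1.0)
    out = (24.0 / np.pi) * np.arccos(arg)
    return out if out.ndim else float(out)


def scale_pet(pet_mm, daylight_h, n_days) -> float | np.ndarray:
    """Rescale reference-interval PET to actual daylight and interval length:
    ``PET' = PET * (L/12) * (D/30)``."""
    out = (
        np.asarray(pet_mm, dtype=float)
        * (np.asarray(daylight_h, dtype=float) / 12.0)
        * (np.asarray(n_days, dtype=float) / 30.0)
    )
    return out if out.ndim else float(out)


def pet_series(
    temp: SubAnnualSeries, site: SiteMeta, calendar: IntervalCalendar
) -> SubAnnualSeries:
    """Per-interval PET (mm) aligned with a temperature series.

    The heat index and exponent are computed per calendar year of the series
    (year-resolved rather than climatological), then each interval's PET is
    scaled by its daylight hours and day count.
    """
    if temp.kind != "temp_mean_c":
        raise ValueError(f"expected a temp_mean_c series, got {temp.kind}")
    if temp.n_intervals != calendar.n_intervals:
        raise ShapeError(
            f"series has {temp.n_intervals} intervals but calendar has {calendar.n_intervals}"
        )
    t = temp.values
    i = heat_index(t, calendar.n_intervals)  # (Y,)
    a = exponent_a(i)
    raw = pet_unscaled(t, i[:, None], a[:, None])
    decl = solar_declination(calendar.median_julian)
    daylight = day_length(site.lat, decl)
    scaled = scale_pet(raw, daylight[None, :], calendar.day_counts[None, :])
    return SubAnnualSeries(scaled, kind="pet_mm", epoch=temp.epoch)


def net_rainfall(precip: SubAnnualSeries, pet: SubAnnualSeries) -> SubAnnualSeries:
    """Net rainfall = precipitation - potential evapotranspiration
    (mm per interval; may be negative)."""
    if precip.values.shape != pet.values.shape:
        raise ShapeError(
            f"precip shape {precip.values.shape} != pet shape {pet.values.shape}"
        )
    return SubAnnualSeries(precip.values - pet.values, kind="net_mm", epoch=precip.epoch)


class ThornthwaitePET(BaseEstimator):
    """Estimator-style wrapper computing interval PET for one site.

    A stateless transformer: ``transform`` maps a mean-temperature
    sub-annual series to the aligned PET series.

    Parameters
    ----------
    site : SiteMeta
        Provides the latitude for the day-length correction.
    calendar : IntervalCalendar
        Interval day counts and median Julian dates.
    """

    def __init__(self, site: SiteMeta, calendar: IntervalCalendar):
        self.site = site
        self.calendar = calendar

    def fit(self, X=None, y=None):
        return self

    def transform(self, temp: SubAnnualSeries) -> SubAnnualSeries:
        return pet_series(temp, self.site, self.calendar)
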