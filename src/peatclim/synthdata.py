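"""Synthetic fixtures with analytically known statistics.

Everything the pipeline consumes — daily observations, Holocene anomaly
grids, per-period scaler tables — can be generated here so every stage is
testable without downloading station records, the anomaly reconstruction or
GCM output. The daily fixture's monthly statistics (wet-day probability,
mean wet-day amount, mean temperature) follow in closed form from its
parameters, which is what the generator-recovery tests check against.

Defaults emulate an oceanic Scottish-Highlands climate: winter-wet
occurrence, gamma-distributed wet-day amounts totalling ~1100 mm yr^-1, a
mild seasonal temperature cycle around 8.5 degC. The fixtures make no claim
of physical realism beyond these first-order statistics.
"""

from __future__ import annotations

import dataclasses
import datetime

import numpy as np

from .aggregate import IntervalCalendar, make_calendar
from .types import AnomalySeries, DailySeries, DAYS_PER_YEAR, ScalerSet, ShapeError, ValidationError

#: Coldest day of year of the sinusoidal temperature cycle (mid-January).
_COLD_DOY = 15.0

#: Default monthly wet-day probabilities (winter-wet oceanic shape).
_DEFAULT_WET_PROB = (0.62, 0.58, 0.55, 0.50, 0.46, 0.44, 0.46, 0.50, 0.54, 0.62, 0.64, 0.65)


@dataclasses.dataclass
class SynthWeatherParams:
    """Parameters of the synthetic daily-weather fixture.

    The daily mean temperature is
    ``annual_mean_c - seasonal_amp_c * cos(2 pi (doy - 15) / 365)`` plus
    N(0, noise_sd_c) noise; tmax/tmin sit half the diurnal range above/below
    it (so tmin <= tmax always holds and monthly mean temperature is exactly
    the seasonal curve averaged over the month). Wet days are independent
    Bernoulli draws with a per-month probability; wet-day amounts are
    gamma(shape, scale) shifted above the trace threshold.
    """

    annual_mean_c: float = 8.5
    seasonal_amp_c: float = 5.5
    wet_prob: tuple = _DEFAULT_WET_PROB
    gamma_shape: float = 0.8
    gamma_scale: float = 7.0
    diurnal_range_c: float = 6.0
    noise_sd_c: float = 1.2
    wet_threshold_mm: float = 0.1

    def __post_init__(self):
        self.wet_prob = np.asarray(self.wet_prob, dtype=float)
        if self.wet_prob.size != 12:
            raise ShapeError("wet_prob needs 12 monthly values")
        if np.any((self.wet_prob < 0) | (self.wet_prob > 1)):
            raise ValidationError("wet probabilities must lie in [0, 1]")
        for name in ("gamma_shape", "gamma_scale", "diurnal_range_c"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.noise_sd_c < 0:
            raise ValidationError("noise_sd_c must be >= 0")

    # ---- analytic truths -------------------------------------------------
    def seasonal_temp(self, doy) -> np.ndarray:
        """True daily mean temperature (noise-free) at a day of year."""
        return self.annual_mean_c - self.seasonal_amp_c * np.cos(
            2.0 * np.pi * (np.asarray(doy, dtype=float) - _COLD_DOY) / DAYS_PER_YEAR
        )

    def monthly_mean_temp(self, calendar: IntervalCalendar | None = None) -> np.ndarray:
        """True mean temperature per month (seasonal curve averaged over the
        month's days)."""
        cal = calendar or make_calendar(12)
        t = self.seasonal_temp(np.arange(1, DAYS_PER_YEAR + 1))
        return np.add.reduceat(t, cal.starts - 1) / cal.day_counts

    @property
    def mean_wet_amount_mm(self) -> float:
        """True mean wet-day precipitation depth."""
        return self.wet_threshold_mm + self.gamma_shape * self.gamma_scale


def make_synthetic_obs(
    params: SynthWeatherParams, n_years: int, seed: int
) -> DailySeries:
    """Generate a synthetic daily observation series (365-day years)."""
    if n_years < 1:
        raise ValidationError("n_years must be >= 1")
    n_days = n_years * DAYS_PER_YEAR
    rng = np.random.default_rng(seed)
    cal = make_calendar(12)
    doy = np.arange(n_days) % DAYS_PER_YEAR + 1
    month = cal.interval_of_day[doy - 1]

    wet = rng.random(n_days) < params.wet_prob[month]
    precip = np.zeros(n_days)
    n_wet = int(wet.sum())
    if n_wet:
        precip[wet] = params.wet_threshold_mm + rng.gamma(
            params.gamma_shape, params.gamma_scale, size=n_wet
        )

    tmean = params.seasonal_temp(doy)
    if params.noise_sd_c > 0:
        tmean = tmean + rng.normal(0.0, params.noise_sd_c, size=n_days)
    half = 0.5 * params.diurnal_range_c
    return DailySeries(
        precip_mm=precip,
        tmin_c=tmean - half,
        tmax_c=tmean + half,
        start_date=datetime.date(2001, 1, 1),
    )


def holocene_like_profile() -> tuple[np.ndarray, np.ndarray]:
    """A canned anomaly profile with the qualitative Holocene shape for
    north-west Europe: cold and dry early Holocene warming ~4 degC over the
    first four millennia, a mid-Holocene wet period, and near-zero anomalies
    at the present. Returns (dtemp_c, dprecip_mm_day) for ages 0..12000 BP
    ascending."""
    #       age:    0     1k    2k    3k    4k    5k    6k    7k    8k    9k   10k   11k   12k
    dtemp = np.array(
        [0.0, 0.1, 0.2, 0.2, 0.1, 0.0, -0.1, -0.2, -0.4, -1.2, -2.2, -3.2, -4.2]
    )
    dprec = np.array(
        [0.0, 0.1, 0.3, 0.4, 0.45, 0.4, 0.35, 0.2, -0.1, -0.5, -0.9, -0.7, -0.5]
    )
    return dtemp, dprec


def make_synthetic_anomaly(
    profile: tuple | None = None, cell: tuple[int, int] = (-5, 58)
) -> AnomalySeries:
    """Build an anomaly series from 13 (dT, dP) knot pairs (ages ascending
    from 0 BP); defaults to the Holocene-like canned profile."""
    if profile is None:
        dtemp, dprec = holocene_like_profile()
    else:
        dtemp, dprec = (np.asarray(p, dtype=float) for p in profile)
    if dtemp.size != 13 or dprec.size != 13:
        raise ShapeError("profile needs 13 knot pairs (ages 0..12000 BP)")
    return AnomalySeries(
        cell=cell,
        ages_bp=np.asarray(AnomalySeries.EXPECTED_AGES, dtype=float),
        dtemp_c=dtemp,
        dprecip_mm_day=dprec,
    )


def make_zero_anomaly_grid(cells=((-5, 58), (-4, 58))) -> dict:
    """An identity-modulation anomaly grid (all knots zero)."""
    zero = np.zeros(13)
    return {
        tuple(c): make_synthetic_anomaly((zero, zero), cell=tuple(c)) for c in cells
    }


def make_synthetic_scalers(
    dtemp_final,
    dprecip_rel_final,
    n_periods: int = 7,
    first_period: tuple[int, int] = (2021, 2040),
) -> list[ScalerSet]:
    """Scaler sets ramping linearly from zero to an end state across decadal
    periods (2021-2040, 2031-2050, ... by default)."""
    if n_periods < 1:
        raise ValidationError("n_periods must be >= 1")
    dt = np.asarray(dtemp_final, dtype=float)
    dp = np.asarray(dprecip_rel_final, dtype=float)
    if dt.shape != dp.shape:
        raise ShapeError("end-state arrays must share a shape")
    sets = []
    for i in range(1, n_periods + 1):
        frac = i / n_periods
        period = (first_period[0] + 10 * (i - 1), first_period[1] + 10 * (i - 1))
        sets.append(ScalerSet(period=period, dtemp_c=frac * dt, dprecip_rel=frac * dp))
    return sets
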