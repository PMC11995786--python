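"""Delta-change climate-scenario scalers and their temporal interpolation.

For each projection period (decadal windows 2021-2040 ... 2081-2100) a
scaler set holds, per sub-annual interval, the additive temperature delta
and the relative precipitation delta between the future and baseline
climatologies. Interpolating each interval's scalers across periods — with
a zero-valued anchor at projection year 0 (2000 CE) — yields a smooth
100-year trajectory that ramps the tail of the baseline series from the
current climate into the scenario while preserving how seasonality is
projected to change (each interval's trajectory depends only on that
interval's own knots).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.interpolate import make_interp_spline
from sklearn.base import BaseEstimator

from .types import ScalerSet, ScalerTrajectory, ShapeError, SubAnnualSeries, ValidationError

log = logging.getLogger(__name__)

#: Projection year 0 of the scaler timeline.
REFERENCE_YEAR_CE = 2000
#: Clip value applied when spline overshoot drives a relative precipitation
#: delta to -1 or below.
_DP_REL_FLOOR = -0.999


def interval_climatology(series: SubAnnualSeries) -> np.ndarray:
    """Per-interval mean over all years of a sub-annual series."""
    if series.n_years < 1:
        raise ValidationError("series is empty")
    return series.values.mean(axis=0)


def temp_scalers(base_profile, future_profile) -> np.ndarray:
    """Additive temperature deltas, future minus baseline (signed)."""
    base = np.asarray(base_profile, dtype=float)
    future = np.asarray(future_profile, dtype=float)
    if base.shape != future.shape:
        raise ShapeError(f"profile shapes differ: {base.shape} vs {future.shape}")
    return future - base


def precip_scalers(base_profile, future_profile) -> np.ndarray:
    """Relative precipitation deltas, (future - baseline) / baseline."""
    base = np.asarray(base_profile, dtype=float)
    future = np.asarray(future_profile, dtype=float)
    if base.shape != future.shape:
        raise ShapeError(f"profile shapes differ: {base.shape} vs {future.shape}")
    if np.any(base <= 0):
        bad = int(np.flatnonzero(base <= 0)[0])
        raise ValidationError(
            f"baseline precipitation mean <= 0 at interval {bad + 1}; relative delta undefined"
        )
    return (future - base) / base


def scalers_from_series(
    period: tuple[int, int],
    base_precip: SubAnnualSeries,
    base_temp: SubAnnualSeries,
    future_precip: SubAnnualSeries,
    future_temp: SubAnnualSeries,
) -> ScalerSet:
    """Build one period's scaler set from baseline and future series."""
    return ScalerSet(
        period=period,
        dtemp_c=temp_scalers(interval_climatology(base_temp), interval_climatology(future_temp)),
        dprecip_rel=precip_scalers(
            interval_climatology(base_precip), interval_climatology(future_precip)
        ),
    )


def interpolate_scalers(sets: list[ScalerSet], horizon_years: int) -> ScalerTrajectory:
    """Interpolate per-interval scalers across projection periods.

    Each interval gets an interpolating spline (cubic where at least four
    knots exist, order-reduced otherwise) through its scaler values anchored
    at the period midpoints, plus a zero-valued anchor at projection year 0;
    the spline is evaluated at projection years 1..horizon. Beyond the last
    anchor the trajectory holds the final knot value.
    """
    if not sets:
        raise ValidationError("at least one scaler set is required")
    sets = sorted(sets, key=lambda s: s.anchor_year)
    n = sets[0].n_intervals
    if any(s.n_intervals != n for s in sets):
        raise ShapeError("scaler sets have differing interval counts")
    # periods may overlap as windows (decadal steps of 20-year windows are
    # the norm) but their midpoints must be distinct and ordered
    x = np.array([0.0] + [s.anchor_year - REFERENCE_YEAR_CE for s in sets])
    if np.any(np.diff(x) <= 0):
        raise ValidationError(
            "period midpoints must be strictly increasing and later than the "
            f"reference year {REFERENCE_YEAR_CE}"
        )
    years = np.arange(1, horizon_years + 1, dtype=float)
    eval_x = np.minimum(years, x[-1])  # hold constant past the last anchor
    k = min(3, x.size - 1)

    dT = np.empty((horizon_years, n))
    dP = np.empty((horizon_years, n))
    for j in range(n):
        yT = np.concatenate(([0.0], [s.dtemp_c[j] for s in sets]))
        yP = np.concatenate(([0.0], [s.dprecip_rel[j] for s in sets]))
        dT[:, j] = make_interp_spline(x, yT, k=k)(eval_x)
        dP[:, j] = make_interp_spline(x, yP, k=k)(eval_x)
    if np.any(dP <= -1):
        n_bad = int((dP <= -1).sum())
        log.warning(
            "spline overshoot drove %d relative precipitation deltas to <= -1; "
            "clipped to %.3f", n_bad, _DP_REL_FLOOR,
        )
        dP = np.where(dP <= -1, _DP_REL_FLOOR, dP)
    return ScalerTrajectory(dtemp_c=dT, dprecip_rel=dP)


def apply_scenario(
    precip_tail: SubAnnualSeries,
    temp_tail: SubAnnualSeries,
    trajectory: ScalerTrajectory,
) -> tuple[SubAnnualSeries, SubAnnualSeries]:
    """Modulate the tail of the baseline elementwise with the trajectory:
    additive for temperature, multiplicative ``(1 + delta)`` for
    precipitation."""
    shape = (trajectory.horizon_years, trajectory.n_intervals)
    if precip_tail.values.shape != shape or temp_tail.values.shape != shape:
        raise ShapeError(
            f"tail shapes {precip_tail.values.shape}/{temp_tail.values.shape} "
            f"do not match trajectory shape {shape}"
        )
    precip = SubAnnualSeries(
        precip_tail.values * (1.0 + trajectory.dprecip_rel),
        kind="precip_total_mm",
        epoch=precip_tail.epoch,
    )
    temp = SubAnnualSeries(
        temp_tail.values + trajectory.dtemp_c,
        kind="temp_mean_c",
        epoch=temp_tail.epoch,
    )
    return precip, temp


class ScenarioModulator(BaseEstimator):
    """Estimator-style wrapper: fit a scaler trajectory from per-period
    scaler sets, then transform (precip, temp) baseline tails.

    Parameters
    ----------
    horizon_years : int, default 100
        Length of the projection tail in years.

    Attributes
    ----------
    trajectory_ : ScalerTrajectory
        The interpolated per-year, per-interval scalers.
    """

    def __init__(self, horizon_years: int = 100):
        self.horizon_years = horizon_years

    def fit(self, scaler_sets: list[ScalerSet], y=None) -> "ScenarioModulator":
        self.trajectory_ = interpolate_scalers(scaler_sets, self.horizon_years)
        return self

    def transform(self, tail: tuple[SubAnnualSeries, SubAnnualSeries]):
        if not hasattr(self, "trajectory_"):
            raise RuntimeError("ScenarioModulator is not fitted; call fit() first")
        return apply_scenario(tail[0], tail[1], self.trajectory_)
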