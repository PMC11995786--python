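"""Holocene paleoclimate anomaly modulation of the historical baseline.

The millennial anomaly reconstruction supplies, per 1-degree grid cell, 13
knots (0..12000 years BP) of temperature anomaly (degC) and daily
precipitation anomaly (mm day^-1) relative to the present. 0 BP is
identified with 2000 CE. The knots are downscaled to annual resolution with
an interpolating cubic spline (exact at the knots) and applied by piecewise
addition: additive for temperature, and for precipitation the daily-rate
anomaly is converted to an interval total with the interval's day count so
the annual anomaly total is conserved exactly. Anomalies carry no seasonal
structure: each year's value is shared by all of its intervals.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.interpolate import make_interp_spline
from sklearn.base import BaseEstimator

from .aggregate import IntervalCalendar
from .types import (
    AnomalySeries,
    CoverageError,
    DenseAnomaly,
    ShapeError,
    SiteMeta,
    SubAnnualSeries,
    ValidationError,
)

log = logging.getLogger(__name__)

#: Span of the reconstruction in years (12 ka BP to present).
HOLOCENE_SPAN_YEARS = 12000


def select_grid_cell(site: SiteMeta, grid: dict[tuple[int, int], AnomalySeries]) -> AnomalySeries:
    """The anomaly series of the 1-degree cell containing the site.

    Cells are half-open boxes [lon_floor, lon_floor+1) x [lat_floor,
    lat_floor+1); a site exactly on a lower-left corner belongs to that cell.
    """
    key = site.grid_cell
    try:
        return grid[key]
    except KeyError:
        raise CoverageError(
            f"no anomaly grid cell covers site {site.name!r} at "
            f"(lon={site.lon}, lat={site.lat}); needed cell {key}"
        ) from None


def downscale_anomaly(
    anomaly: AnomalySeries, n_years: int = HOLOCENE_SPAN_YEARS, n_intervals: int = 12
) -> DenseAnomaly:
    """Downscale millennial anomaly knots to the working (year, interval) grid.

    An interpolating cubic spline through (age, anomaly) is evaluated at the
    integer age of each series year: year ``y`` of ``n_years`` has age
    ``n_years - y``, so the final year evaluates at 0 BP exactly and, at
    full scale, every millennial year reproduces its knot value exactly.
    Runs shorter than the full span cover the most recent part of the
    reconstruction.
    """
    if not 1 <= n_years <= HOLOCENE_SPAN_YEARS:
        raise ValidationError(
            f"n_years must be in [1, {HOLOCENE_SPAN_YEARS}], got {n_years}"
        )
    ages = np.asarray(n_years, dtype=float) - np.arange(1, n_years + 1, dtype=float)
    spl_t = make_interp_spline(anomaly.ages_bp, anomaly.dtemp_c, k=3)
    spl_p = make_interp_spline(anomaly.ages_bp, anomaly.dprecip_mm_day, k=3)
    dT = np.repeat(spl_t(ages)[:, None], n_intervals, axis=1)
    dP = np.repeat(spl_p(ages)[:, None], n_intervals, axis=1)
    return DenseAnomaly(dtemp_c=dT, dprecip_mm_day=dP)


def apply_paleo(
    precip: SubAnnualSeries,
    temp: SubAnnualSeries,
    dense: DenseAnomaly,
    calendar: IntervalCalendar,
) -> tuple[SubAnnualSeries, SubAnnualSeries]:
    """Piecewise-add the dense anomalies to the historical baseline.

    Temperature: ``temp + dT``. Precipitation: ``max(0, precip + dP * D_n)``
    where ``D_n`` is the interval's day count; interval totals floored at
    zero are counted and logged.
    """
    shape = (dense.n_years, dense.n_intervals)
    if precip.values.shape != shape or temp.values.shape != shape:
        raise ShapeError(
            f"series shapes {precip.values.shape}/{temp.values.shape} do not "
            f"match anomaly shape {shape}"
        )
    if dense.n_intervals != calendar.n_intervals:
        raise ShapeError(
            f"anomaly has {dense.n_intervals} intervals but calendar has {calendar.n_intervals}"
        )
    new_t = temp.values + dense.dtemp_c
    raw_p = precip.values + dense.dprecip_mm_day * calendar.day_counts[None, :]
    floored = raw_p < 0
    if floored.any():
        log.info(
            "paleo modulation floored %d of %d precipitation cells at 0 mm",
            int(floored.sum()), raw_p.size,
        )
    new_p = np.maximum(raw_p, 0.0)
    return (
        SubAnnualSeries(new_p, kind="precip_total_mm", epoch=precip.epoch),
        SubAnnualSeries(new_t, kind="temp_mean_c", epoch=temp.epoch),
    )


class PaleoModulator(BaseEstimator):
    """Estimator-style wrapper: select a site's anomaly cell, downscale it,
    and transform (precip, temp) historical series.

    Parameters
    ----------
    site : SiteMeta
    calendar : IntervalCalendar

    Attributes
    ----------
    anomaly_ : AnomalySeries
        The selected grid-cell series.
    dense_ : DenseAnomaly
        Annual-resolution anomalies for the fitted number of years.
    """

    def __init__(self, site: SiteMeta, calendar: IntervalCalendar):
        self.site = site
        self.calendar = calendar

    def fit(self, grid: dict[tuple[int, int], AnomalySeries], n_years: int = HOLOCENE_SPAN_YEARS):
        self.anomaly_ = select_grid_cell(self.site, grid)
        self.dense_ = downscale_anomaly(self.anomaly_, n_years, self.calendar.n_intervals)
        return self

    def transform(self, historical: tuple[SubAnnualSeries, SubAnnualSeries]):
        if not hasattr(self, "dense_"):
            raise RuntimeError("PaleoModulator is not fitted; call fit() first")
        return apply_paleo(historical[0], historical[1], self.dense_, self.calendar)
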