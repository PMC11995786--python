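"""Core data containers for the climate-driver pipeline.

Every container validates its own invariants on construction, so downstream
code can assume: daily precipitation is non-negative, ``tmin <= tmax`` on
every day, sub-annual matrices are complete, anomaly series carry exactly 13
millennial knots, and relative precipitation scalers never reach -1.

All series live on an idealised 365-day (no leap) calendar; observation
readers drop Feb 29 rows on ingest (see :mod:`peatclim.io`).
"""

from __future__ import annotations

import dataclasses
import datetime
import math

import numpy as np

DAYS_PER_YEAR = 365

#: Kinds a sub-annual series may carry. Precipitation and PET are totals in mm
#: per interval and must be non-negative; net rainfall may be negative.
SERIES_KINDS = ("precip_total_mm", "temp_mean_c", "pet_mm", "net_mm")
_NONNEG_KINDS = ("precip_total_mm", "pet_mm")


class ValidationError(ValueError):
    """An input violates a domain-type invariant."""


class ShapeError(ValidationError):
    """Two series that must be aligned have incompatible shapes."""


class GapError(ValidationError):
    """A daily record has missing calendar days."""


class CoverageError(ValidationError):
    """No anomaly grid cell covers the requested site."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise ValidationError(f"{name} contains a non-finite value at row {bad}")
    return arr


@dataclasses.dataclass(frozen=True)
class SiteMeta:
    """Location metadata for one observation site.

    Parameters
    ----------
    name : str
        Non-empty site label.
    lat, lon : float
        Degrees north / east; latitude drives the day-length term of the
        potential-evapotranspiration calculation, and (lon, lat) select the
        1-degree Holocene anomaly grid cell.
    elevation_m : float
        Station elevation in metres above sea level (provenance only).
    """

    name: str
    lat: float
    lon: float
    elevation_m: float = 0.0

    def __post_init__(self):
        if not self.name:
            raise ValidationError("site name must be non-empty")
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValidationError(f"longitude {self.lon} outside [-180, 180]")
        if self.elevation_m < 0:
            raise ValidationError(f"elevation {self.elevation_m} must be >= 0")

    @property
    def grid_cell(self) -> tuple[int, int]:
        """(lon_floor, lat_floor) of the containing 1-degree cell (half-open
        on the upper edges)."""
        return (math.floor(self.lon), math.floor(self.lat))


@dataclasses.dataclass
class DailySeries:
    """A continuous daily record of precipitation and min/max temperature.

    The series is indexed on the 365-day no-leap calendar. ``start_date``
    records real-world provenance; the day-of-year cycle is derived from it
    (Feb 29 never occurs internally).
    """

    precip_mm: np.ndarray
    tmin_c: np.ndarray
    tmax_c: np.ndarray
    start_date: datetime.date = datetime.date(2001, 1, 1)

    def __post_init__(self):
        self.precip_mm = _as_float_array(self.precip_mm, "precip_mm")
        self.tmin_c = _as_float_array(self.tmin_c, "tmin_c")
        self.tmax_c = _as_float_array(self.tmax_c, "tmax_c")
        n = self.precip_mm.size
        if self.tmin_c.size != n or self.tmax_c.size != n:
            raise ShapeError(
                f"column lengths differ: precip {n}, tmin {self.tmin_c.size}, "
                f"tmax {self.tmax_c.size}"
            )
        if n < DAYS_PER_YEAR:
            raise ValidationError(f"daily series must span >= 365 days, got {n}")
        if np.any(self.precip_mm < 0):
            bad = int(np.flatnonzero(self.precip_mm < 0)[0])
            raise ValidationError(f"negative precipitation at row {bad}")
        viol = self.tmin_c > self.tmax_c
        if np.any(viol):
            bad = int(np.flatnonzero(viol)[0])
            raise ValidationError(
                f"tmin ({self.tmin_c[bad]:g}) > tmax ({self.tmax_c[bad]:g}) at row {bad}"
            )

    @property
    def n_days(self) -> int:
        return self.precip_mm.size

    @property
    def n_years(self) -> int:
        """Number of complete 365-day years."""
        return self.n_days // DAYS_PER_YEAR

    @property
    def start_doy(self) -> int:
        """1-based day-of-year of the first record on the no-leap calendar."""
        d = self.start_date
        ref = datetime.date(2001, d.month, 28 if (d.month, d.day) == (2, 29) else d.day)
        return ref.timetuple().tm_yday

    @property
    def day_of_year(self) -> np.ndarray:
        """1..365 for every day of the series."""
        return (self.start_doy - 1 + np.arange(self.n_days)) % DAYS_PER_YEAR + 1

    @property
    def tmean_c(self) -> np.ndarray:
        """Daily mean temperature, (tmin + tmax) / 2."""
        return 0.5 * (self.tmin_c + self.tmax_c)


@dataclasses.dataclass
class SubAnnualSeries:
    """A years x intervals matrix of one aggregated climate variable.

    ``epoch`` is the signed calendar year of the first row (astronomical
    numbering: 2000 CE is 2000, 10,000 BCE is -9999); ``None`` when the
    series is not anchored to the timeline.
    """

    values: np.ndarray
    kind: str
    epoch: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError(f"values must be 2-D (years x intervals), got {self.values.shape}")
        if self.kind not in SERIES_KINDS:
            raise ValidationError(f"unknown series kind {self.kind!r}; expected one of {SERIES_KINDS}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"{self.kind} series contains non-finite cells")
        if self.kind in _NONNEG_KINDS and np.any(self.values < 0):
            y, n = np.argwhere(self.values < 0)[0]
            raise ValidationError(f"{self.kind} is negative at year {y + 1}, interval {n + 1}")

    @property
    def n_years(self) -> int:
        return self.values.shape[0]

    @property
    def n_intervals(self) -> int:
        return self.values.shape[1]


@dataclasses.dataclass
class AnomalySeries:
    """Holocene climate anomalies for one 1-degree grid cell.

    Thirteen knots at 0, 1000, ..., 12000 years BP (0 BP == 2000 CE) holding
    the temperature anomaly (degC) and daily precipitation anomaly
    (mm day^-1) relative to the present-day reference.
    """

    cell: tuple[int, int]
    ages_bp: np.ndarray
    dtemp_c: np.ndarray
    dprecip_mm_day: np.ndarray

    EXPECTED_AGES = tuple(range(0, 12001, 1000))

    def __post_init__(self):
        self.cell = (int(self.cell[0]), int(self.cell[1]))
        self.ages_bp = np.asarray(self.ages_bp, dtype=float)
        self.dtemp_c = _as_float_array(self.dtemp_c, "dtemp_c")
        self.dprecip_mm_day = _as_float_array(self.dprecip_mm_day, "dprecip_mm_day")
        if self.ages_bp.size != 13 or self.dtemp_c.size != 13 or self.dprecip_mm_day.size != 13:
            raise ShapeError(
                f"anomaly series for cell {self.cell} needs exactly 13 knots, "
                f"got {self.ages_bp.size}"
            )
        order = np.argsort(self.ages_bp)
        self.ages_bp = self.ages_bp[order]
        self.dtemp_c = self.dtemp_c[order]
        self.dprecip_mm_day = self.dprecip_mm_day[order]
        if not np.array_equal(self.ages_bp, np.asarray(self.EXPECTED_AGES, dtype=float)):
            raise ValidationError(
                f"anomaly knots for cell {self.cell} must be 0..12000 BP in 1000-year "
                f"steps, got {self.ages_bp.tolist()}"
            )


@dataclasses.dataclass
class ScalerSet:
    """Per-interval future-minus-baseline climate deltas for one projection
    period.

    ``dtemp_c`` is additive (degC); ``dprecip_rel`` is the relative
    precipitation change, applied multiplicatively as ``(1 + dprecip_rel)``
    and therefore constrained to exceed -1.
    """

    period: tuple[int, int]
    dtemp_c: np.ndarray
    dprecip_rel: np.ndarray

    def __post_init__(self):
        self.period = (int(self.period[0]), int(self.period[1]))
        if self.period[1] < self.period[0]:
            raise ValidationError(f"period {self.period} ends before it starts")
        self.dtemp_c = _as_float_array(self.dtemp_c, "dtemp_c")
        self.dprecip_rel = _as_float_array(self.dprecip_rel, "dprecip_rel")
        if self.dtemp_c.size != self.dprecip_rel.size:
            raise ShapeError("dtemp_c and dprecip_rel must have equal interval counts")
        if np.any(self.dprecip_rel <= -1):
            bad = int(np.flatnonzero(self.dprecip_rel <= -1)[0])
            raise ValidationError(
                f"dprecip_rel <= -1 at interval {bad + 1}: modulated precipitation "
                "would go negative"
            )

    @property
    def n_intervals(self) -> int:
        return self.dtemp_c.size

    @property
    def anchor_year(self) -> float:
        """Period midpoint in CE (e.g. 2030.5 for 2021-2040)."""
        return 0.5 * (self.period[0] + self.period[1])


@dataclasses.dataclass
class ScalerTrajectory:
    """Interpolated per-projection-year, per-interval scaler series."""

    dtemp_c: np.ndarray
    dprecip_rel: np.ndarray

    def __post_init__(self):
        self.dtemp_c = np.asarray(self.dtemp_c, dtype=float)
        self.dprecip_rel = np.asarray(self.dprecip_rel, dtype=float)
        if self.dtemp_c.ndim != 2 or self.dtemp_c.shape != self.dprecip_rel.shape:
            raise ShapeError(
                f"trajectory grids must share a 2-D shape, got {self.dtemp_c.shape} "
                f"and {self.dprecip_rel.shape}"
            )
        if np.any(self.dprecip_rel <= -1):
            raise ValidationError("interpolated dprecip_rel <= -1 (should have been clipped)")

    @property
    def horizon_years(self) -> int:
        return self.dtemp_c.shape[0]

    @property
    def n_intervals(self) -> int:
        return self.dtemp_c.shape[1]


@dataclasses.dataclass
class DenseAnomaly:
    """Holocene anomalies downscaled to the working (year, interval) grid.

    Anomalies are annual-mean values broadcast across the intervals of each
    year (the millennial reconstruction carries no seasonal signal).
    """

    dtemp_c: np.ndarray
    dprecip_mm_day: np.ndarray

    def __post_init__(self):
        self.dtemp_c = np.asarray(self.dtemp_c, dtype=float)
        self.dprecip_mm_day = np.asarray(self.dprecip_mm_day, dtype=float)
        if self.dtemp_c.ndim != 2 or self.dtemp_c.shape != self.dprecip_mm_day.shape:
            raise ShapeError("dense anomaly grids must share a 2-D shape")

    @property
    def n_years(self) -> int:
        return self.dtemp_c.shape[0]

    @property
    def n_intervals(self) -> int:
        return self.dtemp_c.shape[1]


@dataclasses.dataclass
class ClimateDriver:
    """The assembled driver: aligned precipitation, temperature, PET and net
    rainfall over the full timeline (12,100 years at full scale).

    ``first_year`` maps year index 1 to a signed calendar year (astronomical
    numbering; -9999 == 10,000 BCE at full scale).
    """

    site: SiteMeta
    precip: SubAnnualSeries
    temp: SubAnnualSeries
    pet: SubAnnualSeries
    net: SubAnnualSeries
    first_year: int
    seed: int | None = None
    config: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        shapes = {s.values.shape for s in (self.precip, self.temp, self.pet, self.net)}
        if len(shapes) != 1:
            raise ShapeError(f"driver series are misaligned: shapes {sorted(shapes)}")
        expected = ("precip_total_mm", "temp_mean_c", "pet_mm", "net_mm")
        got = (self.precip.kind, self.temp.kind, self.pet.kind, self.net.kind)
        if got != expected:
            raise ValidationError(f"driver series kinds {got} != {expected}")

    @property
    def n_years(self) -> int:
        return self.precip.n_years

    @property
    def n_intervals(self) -> int:
        return self.precip.n_intervals

    def calendar_year(self, year_index: int) -> int:
        """Signed calendar year of a 1-based year index."""
        return self.first_year + (year_index - 1)
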