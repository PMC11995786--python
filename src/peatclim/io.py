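"""Readers and writers for every tabular format the pipeline touches.

All files are plain delimited text (UTF-8, "." decimal separator). Floats
are printed with 17 significant digits so that a write/read round trip
reproduces float64 values exactly, which the stage-chaining equivalence of
the pipeline relies on.

Canonical dialects
------------------
observations   date, precip_mm, tmin_c, tmax_c          (ISO-8601 dates)
anomaly grid   lon, lat, age_bp, dtemp_c, dprec_mm_day  (13 ages per cell)
scaler sets    period_start, period_end, interval, dT_c, dP_rel
sub-annual     year, interval, then any of precip_mm, temp_c, pet_mm, net_mm
driver         year_index, calendar_year, interval, precip_mm, temp_c,
               pet_mm, net_mm  (+ a YAML sidecar with site, seed, config)
"""

from __future__ import annotations

import dataclasses
import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    AnomalySeries,
    ClimateDriver,
    DailySeries,
    GapError,
    ScalerSet,
    ShapeError,
    SiteMeta,
    SubAnnualSeries,
    ValidationError,
)
from .weathergen import WeatherGenerator

FLOAT_FMT = "%.17g"

_OBS_COLUMNS = ("date", "precip_mm", "tmin_c", "tmax_c")
#: SubAnnualSeries.kind <-> file column name
_KIND_TO_COLUMN = {
    "precip_total_mm": "precip_mm",
    "temp_mean_c": "temp_c",
    "pet_mm": "pet_mm",
    "net_mm": "net_mm",
}
_COLUMN_TO_KIND = {v: k for k, v in _KIND_TO_COLUMN.items()}


# ------------------------------------------------------------ observations
def read_daily_obs(
    path,
    column_map: dict[str, str] | None = None,
    fill_policy: str = "reject",
) -> DailySeries:
    """Read a daily observation CSV into a validated :class:`DailySeries`.

    Parameters
    ----------
    path : path-like
    column_map : dict, optional
        Maps canonical names (``date``, ``precip_mm``, ``tmin_c``,
        ``tmax_c``) to the file's column names, adapting e.g. MIDAS-style
        exports.
    fill_policy : {"reject", "climatological"}
        What to do with internal missing values: raise (default), or fill
        with the column's month-of-year mean.

    Notes
    -----
    Rows that are entirely missing at the series edges are trimmed; Feb 29
    rows are dropped so the series lives on the 365-day calendar (continuity
    is validated on the real calendar first).
    """
    if fill_policy not in ("reject", "climatological"):
        raise ValueError(f"unknown fill_policy {fill_policy!r}")
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    column_map = column_map or {}
    rename = {column_map.get(c, c): c for c in _OBS_COLUMNS}
    df = df.rename(columns=rename)
    missing = [c for c in _OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")

    # plain datetime.date parsing: simulated series can extend far beyond the
    # nanosecond-resolution pandas timestamp range
    dates: list[datetime.date] = []
    for row, text in enumerate(df["date"].astype(str)):
        try:
            dates.append(datetime.date.fromisoformat(text))
        except ValueError:
            raise ValidationError(
                f"{path}: malformed date {text!r} at row {row}"
            ) from None

    ordinals = np.array([d.toordinal() for d in dates], dtype=np.int64)
    gaps = np.diff(ordinals)
    # a 2-day step onto Mar 1 is fine: files written on the 365-day calendar
    # legitimately skip Feb 29
    skips_leap = np.array(
        [g == 2 and d.month == 3 and d.day == 1 for g, d in zip(gaps, dates[1:])]
    ) if len(dates) > 1 else np.zeros(0, bool)
    bad = (gaps != 1) & ~skips_leap
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1
        raise GapError(
            f"{path}: gap in daily dates between {dates[row - 1]} "
            f"and {dates[row]} (row {row})"
        )

    vals = df[["precip_mm", "tmin_c", "tmax_c"]].apply(pd.to_numeric, errors="coerce")
    all_missing = vals.isna().all(axis=1).to_numpy()
    lo, hi = 0, len(df)
    while lo < hi and all_missing[lo]:
        lo += 1
    while hi > lo and all_missing[hi - 1]:
        hi -= 1
    vals, dates = vals.iloc[lo:hi], dates[lo:hi]
    months = np.array([d.month for d in dates])
    days = np.array([d.day for d in dates])

    na = vals.isna()
    if na.any().any():
        rows = np.flatnonzero(na.any(axis=1).to_numpy())
        if fill_policy == "reject":
            raise ValidationError(
                f"{path}: {rows.size} row(s) with missing values (first at file "
                f"row {rows[0] + lo}); pass fill_policy='climatological' to fill"
            )
        month = months
        for col in vals.columns:
            x = vals[col].to_numpy()
            for m in np.unique(month[np.isnan(x)]):
                sel = month == m
                x[sel & np.isnan(x)] = np.nanmean(x[sel])
            vals[col] = x

    bad = (vals["tmin_c"] > vals["tmax_c"]).to_numpy()
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"{path}: tmin > tmax at row {row + lo} ({dates[row]})"
        )

    keep = ~((months == 2) & (days == 29))
    return DailySeries(
        precip_mm=vals["precip_mm"].to_numpy()[keep],
        tmin_c=vals["tmin_c"].to_numpy()[keep],
        tmax_c=vals["tmax_c"].to_numpy()[keep],
        start_date=dates[0],
    )


def write_daily_obs(series: DailySeries, path) -> None:
    """Write a daily series in the canonical observation dialect (on the
    365-day calendar: dates skip Feb 29)."""
    dates = []
    d = series.start_date
    while len(dates) < series.n_days:
        if not (d.month == 2 and d.day == 29):
            dates.append(d.isoformat())
        d += datetime.timedelta(days=1)
    df = pd.DataFrame(
        {
            "date": dates,
            "precip_mm": series.precip_mm,
            "tmin_c": series.tmin_c,
            "tmax_c": series.tmax_c,
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


# ------------------------------------------------------------ anomaly grid
def read_anomaly_grid(path) -> dict[tuple[int, int], AnomalySeries]:
    """Read a long-format anomaly CSV into per-cell series.

    Each 1-degree cell must contribute exactly one row per age 0, 1000, ...,
    12000 BP; missing or duplicated (cell, age) pairs raise.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    needed = ["lon", "lat", "age_bp", "dtemp_c", "dprec_mm_day"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    grid: dict[tuple[int, int], AnomalySeries] = {}
    expected = set(AnomalySeries.EXPECTED_AGES)
    for (lon, lat), sub in df.groupby(["lon", "lat"]):
        cell = (int(lon), int(lat))
        ages = sub["age_bp"].to_numpy()
        if len(ages) != len(set(ages)):
            dup = int(pd.Series(ages).loc[pd.Series(ages).duplicated()].iloc[0])
            raise ValidationError(f"{path}: duplicate age {dup} BP for cell {cell}")
        have = set(int(a) for a in ages)
        if have != expected:
            lost = sorted(expected - have)
            raise ValidationError(
                f"{path}: cell {cell} is missing knot age(s) {lost} BP"
            )
        sub = sub.sort_values("age_bp")
        grid[cell] = AnomalySeries(
            cell=cell,
            ages_bp=sub["age_bp"].to_numpy(dtype=float),
            dtemp_c=sub["dtemp_c"].to_numpy(dtype=float),
            dprecip_mm_day=sub["dprec_mm_day"].to_numpy(dtype=float),
        )
    if not grid:
        raise ValidationError(f"{path}: anomaly table is empty")
    return grid


def write_anomaly_grid(grid: dict[tuple[int, int], AnomalySeries], path) -> None:
    rows = []
    for cell in sorted(grid):
        a = grid[cell]
        for age, dt, dp in zip(a.ages_bp, a.dtemp_c, a.dprecip_mm_day):
            rows.append((cell[0], cell[1], int(age), dt, dp))
    pd.DataFrame(rows, columns=["lon", "lat", "age_bp", "dtemp_c", "dprec_mm_day"]).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


# ------------------------------------------------------------- scaler sets
def read_scaler_sets(path) -> list[ScalerSet]:
    """Read per-period scaler tables (one row per period x interval)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    needed = ["period_start", "period_end", "interval", "dT_c", "dP_rel"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    sets = []
    for (start, end), sub in df.groupby(["period_start", "period_end"]):
        sub = sub.sort_values("interval")
        n = len(sub)
        if not np.array_equal(sub["interval"].to_numpy(), np.arange(1, n + 1)):
            raise ValidationError(
                f"{path}: period {int(start)}-{int(end)} intervals must be 1..N "
                "with no gaps"
            )
        sets.append(
            ScalerSet(
                period=(int(start), int(end)),
                dtemp_c=sub["dT_c"].to_numpy(dtype=float),
                dprecip_rel=sub["dP_rel"].to_numpy(dtype=float),
            )
        )
    if not sets:
        raise ValidationError(f"{path}: scaler table is empty")
    return sorted(sets, key=lambda s: s.anchor_year)


def write_scaler_sets(sets: list[ScalerSet], path) -> None:
    rows = []
    for s in sorted(sets, key=lambda x: x.anchor_year):
        for j in range(s.n_intervals):
            rows.append((s.period[0], s.period[1], j + 1, s.dtemp_c[j], s.dprecip_rel[j]))
    pd.DataFrame(rows, columns=["period_start", "period_end", "interval", "dT_c", "dP_rel"]).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


# -------------------------------------------------------- sub-annual series
def write_subannual(series: dict[str, SubAnnualSeries], path) -> None:
    """Write aligned sub-annual series (keyed by kind) to one long table."""
    if not series:
        raise ValidationError("no series to write")
    shapes = {s.values.shape for s in series.values()}
    if len(shapes) != 1:
        raise ShapeError(f"series are misaligned: shapes {sorted(shapes)}")
    (ny, n) = shapes.pop()
    out = {
        "year": np.repeat(np.arange(1, ny + 1), n),
        "interval": np.tile(np.arange(1, n + 1), ny),
    }
    for kind, s in series.items():
        out[_KIND_TO_COLUMN[kind]] = s.values.ravel()
    pd.DataFrame(out).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_subannual(path) -> dict[str, SubAnnualSeries]:
    """Read a sub-annual table back to per-kind series."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for c in ("year", "interval"):
        if c not in df.columns:
            raise ValidationError(f"{path}: missing column {c!r}")
    ny = int(df["year"].max())
    n = int(df["interval"].max())
    if len(df) != ny * n:
        raise ValidationError(f"{path}: expected {ny * n} rows ({ny} years x {n}), got {len(df)}")
    df = df.sort_values(["year", "interval"])
    out = {}
    for col in df.columns:
        if col in _COLUMN_TO_KIND:
            out[_COLUMN_TO_KIND[col]] = SubAnnualSeries(
                df[col].to_numpy(dtype=float).reshape(ny, n), kind=_COLUMN_TO_KIND[col]
            )
    if not out:
        raise ValidationError(f"{path}: no recognised value columns")
    return out


# ------------------------------------------------------------------ driver
def write_driver(driver: ClimateDriver, path) -> None:
    """Write the assembled driver plus a ``<path>.meta.yaml`` provenance
    sidecar recording site, seed and configuration."""
    path = Path(path)
    ny, n = driver.precip.values.shape
    years = np.arange(1, ny + 1)
    df = pd.DataFrame(
        {
            "year_index": np.repeat(years, n),
            "calendar_year": np.repeat(driver.first_year + years - 1, n),
            "interval": np.tile(np.arange(1, n + 1), ny),
            "precip_mm": driver.precip.values.ravel(),
            "temp_c": driver.temp.values.ravel(),
            "pet_mm": driver.pet.values.ravel(),
            "net_mm": driver.net.values.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    meta = {
        "site": dataclasses.asdict(driver.site),
        "first_year": int(driver.first_year),
        "n_years": int(ny),
        "n_intervals": int(n),
        "seed": driver.seed,
        "config": driver.config,
    }
    sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def sidecar_path(path) -> Path:
    return Path(str(path) + ".meta.yaml")


def read_driver(path) -> ClimateDriver:
    """Read a driver file and its sidecar back into a :class:`ClimateDriver`."""
    path = Path(path)
    meta = yaml.safe_load(sidecar_path(path).read_text())
    df = pd.read_csv(path, float_precision="round_trip")
    ny, n = meta["n_years"], meta["n_intervals"]
    if len(df) != ny * n:
        raise ValidationError(f"{path}: expected {ny * n} rows, got {len(df)}")
    df = df.sort_values(["year_index", "interval"])

    def grab(col, kind):
        return SubAnnualSeries(df[col].to_numpy(dtype=float).reshape(ny, n), kind=kind)

    return ClimateDriver(
        site=SiteMeta(**meta["site"]),
        precip=grab("precip_mm", "precip_total_mm"),
        temp=grab("temp_c", "temp_mean_c"),
        pet=grab("pet_mm", "pet_mm"),
        net=grab("net_mm", "net_mm"),
        first_year=meta["first_year"],
        seed=meta["seed"],
        config=meta.get("config") or {},
    )


# ------------------------------------------------------------------- model
def save_model(model: WeatherGenerator, path) -> None:
    """Serialize a fitted generator to a human-readable YAML file."""
    Path(path).write_text(yaml.safe_dump(model.to_dict(), sort_keys=False))


def load_model(path) -> WeatherGenerator:
    return WeatherGenerator.from_dict(yaml.safe_load(Path(path).read_text()))
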