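"""LARS-WG-style stochastic daily weather generator.

The model follows the serial (spell-based) weather-generator family:

* precipitation occurrence is an alternating sequence of dry and wet spells
  whose lengths are drawn from per-month semi-empirical distributions (a
  spell belongs to the month its first day falls in);
* wet-day precipitation amounts come from a per-month empirical quantile
  function;
* daily minimum and maximum temperatures are conditionally normal given the
  day's wet/dry state, with seasonal mean and standard deviation curves each
  modelled as a third-order finite Fourier series over the day of year, and
  standardised residuals carrying lag-1 autocorrelation (plus the observed
  tmin/tmax residual cross-correlation).

Simulated years are 365 days long; there are no leap days.
"""

from __future__ import annotations

import bisect
import warnings

import numpy as np
from scipy.signal import lfilter
from sklearn.base import BaseEstimator

from .aggregate import make_calendar
from .types import DAYS_PER_YEAR, DailySeries, ShapeError, SubAnnualSeries, ValidationError

import datetime

#: Number of histogram bins of the semi-empirical spell-length distributions.
SPELL_BINS = 23

_VARS = ("tmin", "tmax")
_CONDS = (0, 1)  # dry, wet
#: Minimum number of days required to fit a condition-specific temperature
#: model before falling back to the unconditional fit.
_MIN_COND_DAYS = 60
_U_CHUNK = 1 << 16


class SpellLengthDistribution:
    """Semi-empirical distribution of integer spell lengths (>= 1 day).

    Bins 1..22 hold exact lengths; the 23rd bin covers lengths >= 23 and is
    sampled uniformly on the observed tail range. This preserves the
    empirical mean spell length, which the simulated wet-day frequency
    depends on directly.
    """

    def __init__(self, lengths):
        lengths = np.asarray(lengths, dtype=int)
        if lengths.size == 0 or np.any(lengths < 1):
            raise ValidationError("spell lengths must be a non-empty set of integers >= 1")
        counts = np.bincount(np.minimum(lengths, SPELL_BINS), minlength=SPELL_BINS + 1)[1:]
        self.probs = counts / counts.sum()
        tail = lengths[lengths >= SPELL_BINS]
        self.tail_max = int(tail.max()) if tail.size else SPELL_BINS
        self.n_obs = int(lengths.size)
        self._cum = np.cumsum(self.probs).tolist()
        self._cum[-1] = 1.0  # guard fp roundoff

    def sample(self, u: float) -> int:
        """Draw one length from a single uniform variate in [0, 1)."""
        b = bisect.bisect_right(self._cum, u)
        if b < SPELL_BINS - 1:
            return b + 1
        # tail bin: reuse the within-bin position as a second uniform
        lo = self._cum[SPELL_BINS - 2] if SPELL_BINS > 1 else 0.0
        width = self._cum[-1] - lo
        frac = (u - lo) / width if width > 0 else 0.0
        span = self.tail_max - SPELL_BINS + 1
        return SPELL_BINS + min(int(frac * span), span - 1)

    def mean(self) -> float:
        k = np.arange(1, SPELL_BINS + 1, dtype=float)
        k[-1] = 0.5 * (SPELL_BINS + self.tail_max)
        return float(np.dot(self.probs, k))

    def to_dict(self) -> dict:
        return {
            "probs": self.probs.tolist(),
            "tail_max": self.tail_max,
            "n_obs": self.n_obs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpellLengthDistribution":
        obj = cls.__new__(cls)
        obj.probs = np.asarray(d["probs"], dtype=float)
        obj.tail_max = int(d["tail_max"])
        obj.n_obs = int(d["n_obs"])
        obj._cum = np.cumsum(obj.probs).tolist()
        obj._cum[-1] = 1.0
        return obj


class EmpiricalAmounts:
    """Empirical quantile function of wet-day precipitation amounts: the
    inverse CDF with linear interpolation between order statistics."""

    def __init__(self, values):
        values = np.sort(np.asarray(values, dtype=float))
        if values.size == 0 or np.any(values < 0):
            raise ValidationError("amounts must be a non-empty set of non-negative values")
        self.quantiles = values

    def sample_many(self, u: np.ndarray) -> np.ndarray:
        q = self.quantiles
        return np.interp(np.asarray(u, dtype=float) * (q.size - 1), np.arange(q.size), q)

    def mean(self) -> float:
        return float(self.quantiles.mean())

    def to_dict(self) -> dict:
        return {"quantiles": self.quantiles.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "EmpiricalAmounts":
        return cls(d["quantiles"])


def _fourier_design(doy: np.ndarray, order: int) -> np.ndarray:
    w = 2.0 * np.pi * np.asarray(doy, dtype=float) / DAYS_PER_YEAR
    cols = [np.ones_like(w)]
    for k in range(1, order + 1):
        cols.append(np.cos(k * w))
        cols.append(np.sin(k * w))
    return np.column_stack(cols)


class FourierCurve:
    """A finite Fourier series over day of year: mean plus ``order`` harmonic
    cosine/sine pairs, fitted by least squares."""

    def __init__(self, coef: np.ndarray, order: int):
        self.coef = np.asarray(coef, dtype=float)
        self.order = int(order)

    @classmethod
    def fit(cls, doy, values, order: int = 3) -> "FourierCurve":
        X = _fourier_design(doy, order)
        coef, *_ = np.linalg.lstsq(X, np.asarray(values, dtype=float), rcond=None)
        return cls(coef, order)

    def __call__(self, doy) -> np.ndarray:
        return _fourier_design(doy, self.order) @ self.coef


def _lag1_autocorr(z: np.ndarray) -> float:
    if z.size < 3 or np.std(z[:-1]) == 0 or np.std(z[1:]) == 0:
        return 0.0
    r = float(np.corrcoef(z[:-1], z[1:])[0, 1])
    return float(np.clip(np.nan_to_num(r), -0.99, 0.99))


def _spell_runs(wet: np.ndarray):
    """Run-length encode the wet/dry day sequence.

    Returns (is_wet, length, start_index) arrays, one entry per spell."""
    n = wet.size
    change = np.flatnonzero(wet[1:] != wet[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    return wet[starts], ends - starts, starts


class WeatherGenerator(BaseEstimator):
    """Stochastic daily weather generator in the LARS-WG style.

    Fit on a continuous daily observation record, then ``sample`` arbitrarily
    long synthetic daily series with the same monthly occurrence, amount and
    temperature statistics.

    Parameters
    ----------
    wet_threshold_mm : float, default 0.1
        A day is wet when its precipitation strictly exceeds this depth
        (trace-rain convention).
    fourier_order : int, default 3
        Harmonic order of the seasonal temperature mean and sd curves.
    sd_floor_c : float, default 0.01
        Lower bound applied to the seasonal sd curves so they stay strictly
        positive over the year.

    Attributes
    ----------
    dry_spells_, wet_spells_ : list of SpellLengthDistribution or None
        Per-month spell-length distributions (None for months where the
        state never starts a spell; the pooled distribution is used then).
    amounts_ : list of EmpiricalAmounts or None
        Per-month wet-day amount distributions.
    mean_curves_, sd_curves_ : dict
        ``(var, cond) -> FourierCurve`` with ``var`` in {"tmin", "tmax"} and
        ``cond`` 0 (dry) / 1 (wet).
    lag1_ : dict
        Residual lag-1 autocorrelation per variable.
    resid_cross_corr_ : float
        Correlation between the standardised tmin and tmax residuals.
    """

    def __init__(self, wet_threshold_mm: float = 0.1, fourier_order: int = 3,
                 sd_floor_c: float = 0.01):
        self.wet_threshold_mm = wet_threshold_mm
        self.fourier_order = fourier_order
        self.sd_floor_c = sd_floor_c

    # ------------------------------------------------------------------ fit
    def fit(self, obs: DailySeries, y=None) -> "WeatherGenerator":
        if not isinstance(obs, DailySeries):
            raise TypeError("fit expects a DailySeries")
        if obs.n_days < DAYS_PER_YEAR:
            raise ValidationError("observations must span at least one full year")

        cal12 = make_calendar(12)
        doy = obs.day_of_year
        month = cal12.interval_of_day[doy - 1]
        wet = obs.precip_mm > self.wet_threshold_mm

        # --- spells -----------------------------------------------------
        is_wet, lengths, starts = _spell_runs(wet)
        start_month = month[starts]
        self.dry_spells_ = [None] * 12
        self.wet_spells_ = [None] * 12
        for m in range(12):
            for state, target in ((False, self.dry_spells_), (True, self.wet_spells_)):
                sel = lengths[(is_wet == state) & (start_month == m)]
                if sel.size:
                    target[m] = SpellLengthDistribution(sel)
        dry_all = lengths[~is_wet]
        wet_all = lengths[is_wet]
        self.dry_spell_pool_ = SpellLengthDistribution(dry_all) if dry_all.size else None
        self.wet_spell_pool_ = SpellLengthDistribution(wet_all) if wet_all.size else None

        # --- wet-day amounts --------------------------------------------
        self.amounts_ = [None] * 12
        for m in range(12):
            sel = obs.precip_mm[wet & (month == m)]
            if sel.size:
                self.amounts_[m] = EmpiricalAmounts(sel)
            else:
                warnings.warn(
                    f"month {m + 1} has no wet days in the observations; "
                    "simulation falls back to the pooled amount distribution",
                    stacklevel=2,
                )
        pooled = obs.precip_mm[wet]
        self.amount_pool_ = EmpiricalAmounts(pooled) if pooled.size else None

        # --- temperatures ------------------------------------------------
        series = {"tmin": obs.tmin_c, "tmax": obs.tmax_c}
        month_mid_doy = cal12.median_julian
        self.mean_curves_ = {}
        self.sd_curves_ = {}
        self.lag1_ = {}
        z_by_var = {}
        for var, x in series.items():
            z = np.empty(x.size)
            for cond in _CONDS:
                mask = wet == bool(cond)
                use = mask if mask.sum() >= _MIN_COND_DAYS else np.ones(x.size, bool)
                mean_curve = FourierCurve.fit(doy[use], x[use], self.fourier_order)
                resid = x - mean_curve(doy)
                # month-grouped residual sd, smoothed by the Fourier fit
                sds = np.empty(12)
                overall = max(float(np.std(resid[use], ddof=1)), self.sd_floor_c)
                for m in range(12):
                    mm = use & (month == m)
                    sds[m] = np.std(resid[mm], ddof=1) if mm.sum() >= 3 else overall
                sd_curve = FourierCurve.fit(month_mid_doy, np.maximum(sds, self.sd_floor_c),
                                            self.fourier_order)
                self.mean_curves_[(var, cond)] = mean_curve
                self.sd_curves_[(var, cond)] = sd_curve
                sd_d = np.maximum(sd_curve(doy), self.sd_floor_c)
                z[mask] = resid[mask] / sd_d[mask]
            self.lag1_[var] = _lag1_autocorr(z)
            z_by_var[var] = z
        c = np.corrcoef(z_by_var["tmin"], z_by_var["tmax"])[0, 1]
        self.resid_cross_corr_ = float(np.clip(np.nan_to_num(c), -0.999, 0.999))

        self.n_obs_days_ = obs.n_days
        self._warn_degenerate(wet, month)
        return self

    def _warn_degenerate(self, wet, month):
        for m in range(12):
            days = month == m
            if days.any() and not wet[days].any():
                warnings.warn(
                    f"month {m + 1} is entirely dry in the observations; "
                    "its wet-spell model is a point-mass dry model",
                    stacklevel=3,
                )

    # --------------------------------------------------------------- sample
    def sample(self, n_years: int, random_state=None) -> DailySeries:
        """Simulate ``n_years`` of daily weather (365-day years).

        Deterministic for a fixed fitted model, ``n_years`` and
        ``random_state``.
        """
        self._check_fitted()
        if n_years < 1:
            raise ValidationError("n_years must be >= 1")
        n_days = n_years * DAYS_PER_YEAR
        if n_days > np.iinfo(np.int64).max // 64:
            raise ValidationError(f"n_years={n_years} overflows the day index")
        rng = np.random.default_rng(random_state)
        cal12 = make_calendar(12)
        month_of_doy = cal12.interval_of_day  # (365,)

        wet = self._sample_occurrence(n_days, month_of_doy, rng)
        precip = self._sample_amounts(wet, month_of_doy, n_days, rng)
        tmin, tmax = self._sample_temperatures(wet, n_days, rng)
        return DailySeries(
            precip_mm=precip, tmin_c=tmin, tmax_c=tmax,
            start_date=datetime.date(2001, 1, 1),
        )

    def _check_fitted(self):
        if not hasattr(self, "mean_curves_"):
            raise RuntimeError("WeatherGenerator is not fitted; call fit() first")

    def _sample_occurrence(self, n_days, month_of_doy, rng) -> np.ndarray:
        wet = np.zeros(n_days, dtype=bool)
        if self.wet_spell_pool_ is None:
            return wet  # observations were all dry
        if self.dry_spell_pool_ is None:
            wet[:] = True  # observations were all wet
            return wet
        u_buf = rng.random(_U_CHUNK)
        ui = 0
        pos = 0
        cur_wet = False  # series starts in a dry spell by convention
        dry_m, wet_m = self.dry_spells_, self.wet_spells_
        dry_pool, wet_pool = self.dry_spell_pool_, self.wet_spell_pool_
        while pos < n_days:
            if ui == _U_CHUNK:
                u_buf = rng.random(_U_CHUNK)
                ui = 0
            m = month_of_doy[pos % DAYS_PER_YEAR]
            if cur_wet:
                dist = wet_m[m] or wet_pool
            else:
                dist = dry_m[m] or dry_pool
            length = dist.sample(u_buf[ui])
            ui += 1
            end = min(pos + length, n_days)
            if cur_wet:
                wet[pos:end] = True
            pos = end
            cur_wet = not cur_wet
        return wet

    def _sample_amounts(self, wet, month_of_doy, n_days, rng) -> np.ndarray:
        precip = np.zeros(n_days)
        widx = np.flatnonzero(wet)
        if widx.size == 0:
            return precip
        wmonth = month_of_doy[widx % DAYS_PER_YEAR]
        for m in range(12):
            sel = widx[wmonth == m]
            if sel.size == 0:
                continue
            dist = self.amounts_[m] or self.amount_pool_
            precip[sel] = dist.sample_many(rng.random(sel.size))
        # wet days must exceed the threshold; dry days are exactly zero
        np.maximum(precip, np.nextafter(self.wet_threshold_mm, np.inf),
                   out=precip, where=wet)
        return precip

    def _sample_temperatures(self, wet, n_days, rng):
        doy_idx = np.arange(n_days) % DAYS_PER_YEAR  # 0-based
        cond = wet.astype(int)
        grid = np.arange(1, DAYS_PER_YEAR + 1)
        mean_tab = {}
        sd_tab = {}
        for var in _VARS:
            mean_tab[var] = np.stack(
                [self.mean_curves_[(var, c)](grid) for c in _CONDS]
            )  # (2, 365)
            sd_tab[var] = np.stack(
                [np.maximum(self.sd_curves_[(var, c)](grid), self.sd_floor_c)
                 for c in _CONDS]
            )

        r = self.resid_cross_corr_
        s = np.sqrt(1.0 - r * r)
        eps = rng.standard_normal((2, n_days))
        e = {"tmax": eps[0], "tmin": r * eps[0] + s * eps[1]}
        z = {var: self._ar1(e[var], self.lag1_[var]) for var in _VARS}

        vals = {
            var: mean_tab[var][cond, doy_idx] + sd_tab[var][cond, doy_idx] * z[var]
            for var in _VARS
        }
        # enforce tmin <= tmax: redraw the offending days (fresh, uncorrelated
        # in time but keeping the tmin/tmax cross-correlation), then swap
        bad = np.flatnonzero(vals["tmin"] > vals["tmax"])
        for _ in range(100):
            if bad.size == 0:
                break
            e0 = rng.standard_normal(bad.size)
            e1 = rng.standard_normal(bad.size)
            znew = {"tmax": e0, "tmin": r * e0 + s * e1}
            for var in _VARS:
                vals[var][bad] = (
                    mean_tab[var][cond[bad], doy_idx[bad]]
                    + sd_tab[var][cond[bad], doy_idx[bad]] * znew[var]
                )
            bad = bad[vals["tmin"][bad] > vals["tmax"][bad]]
        if bad.size:
            lo = np.minimum(vals["tmin"][bad], vals["tmax"][bad])
            hi = np.maximum(vals["tmin"][bad], vals["tmax"][bad])
            vals["tmin"][bad] = lo
            vals["tmax"][bad] = hi
        return vals["tmin"], vals["tmax"]

    @staticmethod
    def _ar1(e: np.ndarray, rho: float) -> np.ndarray:
        if rho == 0.0:
            return e
        z = lfilter([np.sqrt(1.0 - rho * rho)], [1.0, -rho], e)
        z[0] = e[0]  # stationary start
        return z

    # -------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        """Serializable representation (see :func:`peatclim.io.save_model`)."""
        self._check_fitted()

        def spells(lst):
            return [d.to_dict() if d else None for d in lst]

        return {
            "params": self.get_params(),
            "dry_spells": spells(self.dry_spells_),
            "wet_spells": spells(self.wet_spells_),
            "dry_spell_pool": self.dry_spell_pool_.to_dict() if self.dry_spell_pool_ else None,
            "wet_spell_pool": self.wet_spell_pool_.to_dict() if self.wet_spell_pool_ else None,
            "amounts": [a.to_dict() if a else None for a in self.amounts_],
            "amount_pool": self.amount_pool_.to_dict() if self.amount_pool_ else None,
            "mean_curves": {f"{v}_{c}": self.mean_curves_[(v, c)].coef.tolist()
                            for v in _VARS for c in _CONDS},
            "sd_curves": {f"{v}_{c}": self.sd_curves_[(v, c)].coef.tolist()
                          for v in _VARS for c in _CONDS},
            "lag1": dict(self.lag1_),
            "resid_cross_corr": self.resid_cross_corr_,
            "n_obs_days": self.n_obs_days_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WeatherGenerator":
        model = cls(**d["params"])

        def spells(lst):
            return [SpellLengthDistribution.from_dict(x) if x else None for x in lst]

        model.dry_spells_ = spells(d["dry_spells"])
        model.wet_spells_ = spells(d["wet_spells"])
        model.dry_spell_pool_ = (
            SpellLengthDistribution.from_dict(d["dry_spell_pool"]) if d["dry_spell_pool"] else None
        )
        model.wet_spell_pool_ = (
            SpellLengthDistribution.from_dict(d["wet_spell_pool"]) if d["wet_spell_pool"] else None
        )
        model.amounts_ = [EmpiricalAmounts.from_dict(a) if a else None for a in d["amounts"]]
        model.amount_pool_ = (
            EmpiricalAmounts.from_dict(d["amount_pool"]) if d["amount_pool"] else None
        )
        order = model.fourier_order
        model.mean_curves_ = {
            (v, c): FourierCurve(np.asarray(d["mean_curves"][f"{v}_{c}"]), order)
            for v in _VARS for c in _CONDS
        }
        model.sd_curves_ = {
            (v, c): FourierCurve(np.asarray(d["sd_curves"][f"{v}_{c}"]), order)
            for v in _VARS for c in _CONDS
        }
        model.lag1_ = {k: float(v) for k, v in d["lag1"].items()}
        model.resid_cross_corr_ = float(d["resid_cross_corr"])
        model.n_obs_days_ = int(d["n_obs_days"])
        return model


# ----------------------------------------------------------- thin wrappers
def fit_weathergen(obs: DailySeries, wet_threshold_mm: float = 0.1) -> WeatherGenerator:
    """Fit a :class:`WeatherGenerator` to observations."""
    return WeatherGenerator(wet_threshold_mm=wet_threshold_mm).fit(obs)


def simulate_daily(model: WeatherGenerator, n_years: int, seed: int) -> DailySeries:
    """Simulate a daily series from a fitted model under a fixed seed."""
    return model.sample(n_years, random_state=seed)


# ------------------------------------------------------------- diagnostics
def seasonal_profile(series: SubAnnualSeries) -> np.ndarray:
    """Per-interval mean over all years (the interval climatology)."""
    if series.n_years < 1:
        raise ValidationError("series is empty")
    return series.values.mean(axis=0)


def profile_mae(obs_profile, sim_profile) -> float:
    """Mean absolute error between two interval climatologies."""
    a = np.asarray(obs_profile, dtype=float)
    b = np.asarray(sim_profile, dtype=float)
    if a.shape != b.shape:
        raise ShapeError(f"profile shapes differ: {a.shape} vs {b.shape}")
    return float(np.mean(np.abs(a - b)))


def normalised_bias(obs_profile, sim_profile) -> float:
    """Normalised seasonal bias in percent:
    ``100 * (mean(sim) - mean(obs)) / mean(obs)``."""
    a = np.asarray(obs_profile, dtype=float)
    b = np.asarray(sim_profile, dtype=float)
    if a.shape != b.shape:
        raise ShapeError(f"profile shapes differ: {a.shape} vs {b.shape}")
    if a.mean() == 0:
        raise ValidationError("normalised bias undefined: observed profile mean is zero")
    return float(100.0 * (b.mean() - a.mean()) / a.mean())
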