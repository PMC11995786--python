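# Methods

`peatclim` generates continuous, site-specific, sub-annual climate driver
series — precipitation, temperature, potential evapotranspiration (PET) and
net rainfall — spanning 12,000 historical years plus a 100-year projection,
for use as driving data in process-based peatland models. This note
describes the model components, the choices made where the design was
genuinely open, the defaults and their units, what the synthetic fixtures
do and do not establish, and known limitations.

## Timeline and calendar

All series live on a 365-day year (leap days are dropped on ingest). The
year is partitioned into N sub-annual intervals: N = 12 calendar months, or
N = 52 weeks built as fifty-one 7-day weeks plus a final 8-day week. The
8-day week (rather than discarding day 365) keeps precipitation mass
conservation exact under aggregation. Each interval carries a median Julian
date J_n (the lower middle day for even-length intervals — a deterministic
tie-break) used as its time coordinate for solar geometry.

The full timeline is 12,100 years. Year index 12,000 is 2000 CE, taken as
the present (0 BP); year 1 is therefore 10,000 BCE (astronomical year
−9999) and year 12,100 is 2100 CE. Shorter runs, used routinely in tests,
cover the most recent part of the Holocene span.

## Stochastic weather generator

The generator follows the serial, spell-based family of daily weather
generators.

**Occurrence.** A day is wet when precipitation exceeds the trace threshold
(default 0.1 mm, configurable). The day sequence is decomposed into
alternating dry and wet spells; a spell belongs to the month its first day
falls in. Each month holds a semi-empirical spell-length distribution with
23 bins: lengths 1–22 as exact integer bins, and a tail bin covering
lengths ≥ 23 sampled uniformly over the observed tail range. This layout
preserves the empirical mean spell length, on which the simulated wet-day
frequency depends directly; equal-width or quantile bins on heavily tied
small integers do not. Months in which a state never starts a spell fall
back to the pooled all-month distribution; fully degenerate observations
(all dry, or all wet) simulate that state throughout, with a warning at fit
time. Simulated series start in a dry spell by convention.

**Amounts.** Wet-day depths are drawn from each month's empirical quantile
function (linear interpolation between order statistics), with a pooled
fallback for months that had no wet days. Draws are clamped to exceed the
wet threshold so simulated wet days are wet by definition.

**Temperature.** Daily tmin and tmax are conditionally normal given the
day's wet/dry state. The seasonal mean is a third-order finite Fourier
series over day of year, fitted by least squares per variable and
condition (conditions with fewer than 60 days fall back to the
unconditional fit). The seasonal standard deviation is fitted on
month-grouped residuals and smoothed by the same order-3 Fourier fit,
floored at 0.01 °C so it stays strictly positive. Standardised residuals
carry a lag-1 autocorrelation per variable (an AR(1) recursion in
simulation) and the observed tmin–tmax cross-correlation; the paper behind
the original generator family does not pin down the autocorrelation
sub-model, so lag-1 residual correlation is this package's choice. If a
draw yields tmin > tmax, the pair is redrawn for the offending days (fresh
cross-correlated innovations, outside the AR chain) up to 100 times, then
swapped — the redraw locally weakens temporal autocorrelation on those rare
days, which we accept for the guarantee tmin ≤ tmax. Cross-variable
dependence beyond wet/dry conditioning (e.g. amount–temperature) is not
modelled.

**Determinism.** A fixed (model, n_years, seed) triple yields bit-identical
output; uniform variates for the spell loop are consumed from fixed-size
buffers so the draw sequence is reproducible.

**Diagnostics.** `seasonal_profile` (per-interval mean over years),
`profile_mae` (mean absolute error between profiles) and `normalised_bias`
(100 · (mean(sim) − mean(obs)) / mean(obs), in %) quantify how well a
simulation reproduces the training seasonality.

## Aggregation

Daily mean temperature is the midpoint of the daily extremes,
(tmin + tmax)/2. Precipitation is summed within intervals — conserving
annual totals exactly — and daily mean temperature is averaged.

## Scenario scalers and interpolation

For each projection period (decadal steps of 20-year windows, 2021–2040 …
2081–2100), per-interval scalers are computed between the baseline and
future interval climatologies: additive for temperature (signed — a
projected cooling is legitimate), relative for precipitation (undefined,
and rejected, when a baseline interval mean is ≤ 0). Relative precipitation
scalers must exceed −1 so modulated precipitation stays non-negative.

Each interval's scalers are interpolated across periods with an
interpolating spline through (anchor year, value) knots — anchor = period
midpoint, e.g. 2030.5 for 2021–2040, on a projection-year axis with year
0 = 2000 CE — plus a zero-valued anchor at year 0 that enforces a smooth
ramp out of the unmodulated baseline. The spline is cubic with exact knot
reproduction, order-reduced automatically when fewer than four knots exist;
beyond the last anchor the trajectory holds the final value. Spline
overshoot below −1 in the precipitation trajectory is clipped to −0.999
with a logged warning. The trajectory is evaluated per projection year and
held constant within a year; each interval depends only on its own knots,
so the projected change to seasonality is preserved. Application is
elementwise: T′ = T + ΔT(y,n), P′ = P·(1 + ΔP(y,n)).

## Holocene anomaly modulation

The millennial reconstruction supplies, per 1° grid cell (half-open boxes;
a site on a cell's lower-left corner belongs to that cell), 13 knots at
0–12,000 years BP of temperature anomaly (°C) and daily precipitation-rate
anomaly (mm day⁻¹) relative to the present. Sites are matched to their
containing cell only — no spatial interpolation between cells.

Downscaling uses an interpolating cubic spline in age, evaluated at the
integer age of each series year (year y of n has age n − y), so knot years
reproduce knot values exactly and the final year joins the unmodulated
present-day baseline at the 0 BP knot. Anomalies are annual means applied
identically to every interval of a year: the reconstruction carries no
seasonal signal, and a single anomaly series per variable per site is the
source material. Temperature anomalies add directly. Precipitation-rate
anomalies convert to interval totals by the interval's day count (so a
constant rate anomaly contributes exactly 365 × rate per year, independent
of N); totals driven below zero are floored at 0 mm, with floor events
counted and logged.

## Potential evapotranspiration

The monthly Thornthwaite formulation is generalised to any interval count
by treating intervals as month-equivalents: the annual heat index is
I = Σ (max(t_n, 0)/5)^1.514 · (12/N), making I invariant to N for a given
climate. The exponent a is the standard cubic polynomial in I. Interval PET
is 16·(10 t_n/I)^a mm for a reference 30-day interval at 12 h daylight,
scaled by (L_n/12)(D_n/30) with L_n the day length from latitude and solar
declination (degree-form approximation, δ_n = 23.45·sin((J_n−81)·360/365°))
at the interval's median Julian date.

Choices worth flagging: temperatures at or below 0 °C contribute nothing to
I and yield zero PET (standard Thornthwaite practice; early-Holocene
winters demand a rule). I is computed per calendar year of the series
rather than from a long-term climatology, since PET is derived from the
fully modulated year-resolved series. The arccos argument in the day-length
formula is clamped to [−1, 1], implementing polar day/night rather than a
domain error, for generality beyond ~58° N sites. PET is computed after all
modulation, over the whole 12,100-year series, and net rainfall is
precipitation − PET (may be negative).

## Pipeline and provenance

`assemble_driver` runs: fit → simulate (n_past + n_future years) →
aggregate → paleo modulation of years 1..n_past → scenario modulation of
the tail → PET → net rainfall. The junction is continuous by construction:
the paleo anomaly reaches its ≈ 0 present-day knot at the last historical
year and the scenario trajectory ramps from its zero anchor at the same
epoch. One seed drives the single stochastic stage, and the driver file's
sidecar records site, seed and configuration, so a run is exactly
reproducible. All text outputs print floats with 17 significant digits,
which round-trips float64 exactly; chaining the CLI stages through files is
therefore bit-identical to the in-memory pipeline (verified in the tests at
the function + file level).

## Synthetic fixtures

The fixture module emulates all external inputs so the package builds and
tests offline. Daily observations use independent Bernoulli wet days with
per-month probabilities, gamma wet-day amounts, and a sinusoidal daily mean
temperature with iid Gaussian noise and a constant diurnal range — so
monthly wet-day frequency, mean wet-day amount and mean temperature are
known in closed form. Defaults emulate an oceanic Scottish-Highlands
climate: annual mean 8.5 °C, seasonal amplitude 5.5 °C (coldest mid-
January), winter-wet probabilities 0.44–0.65, gamma(0.8, 7.0) amounts above
the 0.1 mm trace threshold (≈ 5.7 mm per wet day, ≈ 1100 mm yr⁻¹), diurnal
range 6 °C, and temperature noise sd 1.2 °C. The noise level is chosen for
analytic tractability of the recovery tests; real daily temperature
residuals in this climate are larger (≈ 2–3 °C), and real precipitation has
heavier tails, spell persistence and temperature coupling that the fixture
deliberately omits. Passing the recovery tests therefore demonstrates that
the generator recovers first-order monthly statistics from data of this
structure — not that it captures every property of real station records.

The canned Holocene-like anomaly profile (cold/dry early Holocene warming
≈ 4 °C over four millennia, a mid-Holocene wet period, near-zero at the
present) and the linearly ramping scaler sets likewise reproduce the
qualitative structure of the real inputs, not their values.

## Numerical choices and degenerate inputs

- Splines: `scipy.interpolate.make_interp_spline`, k = min(3, knots − 1),
  no smoothing — exactness at knots is a tested contract.
- Fourier fits: ordinary least squares on the harmonic design matrix.
- AR(1): `scipy.signal.lfilter`, with the first element replaced by its
  innovation for a unit-variance stationary start.
- Observation ingest: all-missing edge rows are trimmed; internal missing
  values are rejected by default (silent imputation would bias the
  generator) or filled with month-of-year means on request; malformed
  dates, calendar gaps and tmin > tmax are reported with row addresses.
- Sub-annual matrices must be complete; precipitation and PET series are
  validated non-negative at construction.

## Test problem sizes

The suite exercises the full 12,100-year monthly assembly once (the
null-modulation identity); parameter recovery uses a 20-year training
fixture and 1000 simulated years; other pipeline tests use a few hundred
historical years covering the most recent part of the anomaly span. These
sizes were chosen as the smallest that give the Monte-Carlo bounds used in
the assertions.

## Known limitations

- The generator is not a bit-compatible clone of any existing tool; it
  models no radiation or humidity variables.
- Wet/dry conditioning is the only precipitation–temperature coupling.
- Temperature-based PET can be biased outside oceanic/hyperoceanic
  climates; the Penman–Monteith alternative is out of scope because its
  inputs (irradiance, wind) are unavailable at paleo and projection time
  scales.
- Paleo and future modulations are interpolated independently; a single
  spline through both eras would guarantee a smoother junction and is a
  possible refinement.
- No spatial interpolation of the anomaly grid: nearby sites in different
  cells get different Holocene climates.
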