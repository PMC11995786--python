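# peatclim

Peatland ecohydrological models such as DigiBog need continuous,
site-specific climate driving data — precipitation, temperature and
potential evapotranspiration at weekly or monthly resolution — from a
peatland's initiation thousands of years ago through the end of a future
climate projection. Such combined past-and-future series are not available
off the shelf. `peatclim` builds them: a 12,100-year series spanning 10,000
BCE to 2100 CE (2000 CE taken as the present), assembled from

1. a **stochastic daily weather generator** (LARS-WG-style) fitted to daily
   station observations, which simulates an arbitrarily long baseline of
   daily precipitation and min/max temperature with the site's seasonality
   and variability;
2. **Holocene anomaly modulation**: millennial-resolution temperature and
   precipitation anomalies for the site's 1° grid cell, downscaled with an
   interpolating spline and added piecewise to the first 12,000 years;
3. **delta-change scenario scalers**: per-interval differences between a
   future and the baseline climatology, interpolated across projection
   periods into a smooth 100-year trajectory applied to the final century;
4. a **modified Thornthwaite PET** calculation and net rainfall
   (precipitation − PET).

## The model in brief

The year is split into N sub-annual intervals (N = 12 months or 52 weeks;
weeks are 51 × 7 days + one 8-day week so ΣD\_n = 365). Daily series use
365-day years (no leap days).

**Weather generator.** Wet/dry occurrence is an alternating sequence of
spells with per-month semi-empirical length distributions; wet-day amounts
follow each month's empirical quantile function; daily tmin/tmax are
conditionally normal given the wet/dry state, with seasonal mean and
standard-deviation curves fitted as third-order Fourier series over the day
of year and lag-1 autocorrelated residuals.

**Scenario scalers.** For interval n,

    ΔT_n = T̄_n,future − T̄_n,base        (additive, °C)
    ΔP_n = (P̄_n,future − P̄_n,base) / P̄_n,base   (relative)

are interpolated over projection-period midpoints (plus a zero anchor at
year 0 = 2000 CE) with an interpolating spline, then applied per year y and
interval n as `T′ = T + ΔT(y,n)` and `P′ = P · (1 + ΔP(y,n))`.

**Paleoclimate.** Anomaly knots at 0, 1000, …, 12000 years BP are splined
to annual resolution; temperature anomalies add directly, daily
precipitation-rate anomalies convert to interval totals via the interval's
day count and are floored at zero.

**PET.** With t\_n the interval mean temperature,

    I  = Σ_n (max(t_n,0)/5)^1.514 · (12/N)
    a  = 675e-9·I³ − 771e-7·I² + 1792e-5·I + 0.49239
    PET_n  = 16 · (10 t_n / I)^a                (0 for t_n ≤ 0)
    δ_n = 23.45 · sin((J_n − 81)·360/365°)
    L_n = (24/π) · arccos(−tan(lat)·tan(δ_n))
    PET′_n = PET_n · (L_n/12) · (D_n/30)

where J\_n is the interval's median Julian date and D\_n its day count.

## Worked example

```python
import numpy as np
import peatclim as pc

# 1. a 20-year synthetic daily record (stands in for station observations;
#    real data goes through pc.io.read_daily_obs)
params = pc.SynthWeatherParams()
obs = pc.make_synthetic_obs(params, n_years=20, seed=42)

# 2. fit the weather generator and validate its seasonality
model = pc.fit_weathergen(obs, wet_threshold_mm=0.1)
sim = model.sample(1000, random_state=1)
cal = pc.make_calendar(12)
obs_p, obs_t = pc.aggregate_daily(obs, cal)
sim_p, sim_t = pc.aggregate_daily(sim, cal)
print(pc.profile_mae(pc.seasonal_profile(obs_t), pc.seasonal_profile(sim_t)))
print(pc.normalised_bias(pc.seasonal_profile(obs_p), pc.seasonal_profile(sim_p)))

# 3. the full 12,100-year monthly driver
site = pc.SiteMeta("Altnaharra-like", lat=58.288, lon=-4.442, elevation_m=81)
grid = {(-5, 58): pc.make_synthetic_anomaly(cell=(-5, 58))}     # Holocene-like knots
scalers = pc.make_synthetic_scalers(np.full(12, 2.4), np.full(12, 0.05), n_periods=7)
driver = pc.assemble_driver(obs, site, grid, scalers, seed=7)
```

Running the example end to end (with prints of the diagnostics and of the
driver's annual PET/net-rainfall summaries) gives:

```
temperature profile MAE: 0.020 degC
precipitation seasonal bias: -0.73 %
annual PET, years 1-100 (~10 ka BCE):    516.8 mm
annual PET, years 11901-12000 (~today):  621.1 mm
annual net rainfall (~today):            545.6 mm
final-decade warming vs ~today:         +2.44 degC
```

Reading the numbers: the fitted generator reproduces the training
seasonality to 0.02 °C (profile MAE) with a −0.7 % precipitation bias;
annual PET in the cold early Holocene is ~100 mm lower than at present
(the −4 °C temperature anomaly suppresses atmospheric demand); net rainfall
stays strongly positive, as expected for a Scottish blanket-bog climate;
and the +2.4 °C scaler end state appears as the final-decade warming.

The same stages are available from the shell (`peatclim fit | generate |
scalers | scenario | paleo | pet | pipeline`); see `peatclim --help`.

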