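"""End-to-end assembly of the climate driver.

The full-scale timeline is 12,100 years: 12,000 historical years (10,000
BCE to 2000 CE) modulated by the Holocene anomaly reconstruction, followed
by 100 projection years (2001-2100 CE) modulated by the interpolated
scenario scalers. PET is computed after all modulation, then net rainfall.

One seed drives the single stochastic stage (the weather generator), so a
driver plus its provenance sidecar reproduces the run exactly.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .aggregate import aggregate_daily, make_calendar
from .paleo import apply_paleo, downscale_anomaly, select_grid_cell
from .pet import net_rainfall, pet_series
from .scenario import apply_scenario, interpolate_scalers
from .types import (
    AnomalySeries,
    ClimateDriver,
    DailySeries,
    ScalerSet,
    SiteMeta,
    SubAnnualSeries,
    ValidationError,
)
from .weathergen import WeatherGenerator

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Tunable settings of a driver run.

    n_past_years covers the most recent part of the 12,000-year anomaly
    span when shortened; n_future_years is the scenario horizon.
    """

    n_intervals: int = 12
    wet_threshold_mm: float = 0.1
    n_past_years: int = 12000
    n_future_years: int = 100

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def assemble_driver(
    obs: DailySeries,
    site: SiteMeta,
    anomaly_grid: dict[tuple[int, int], AnomalySeries],
    scaler_sets: list[ScalerSet],
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> ClimateDriver:
    """Run the full pipeline: fit, simulate, aggregate, modulate, derive.

    Stages: (1) fit the weather generator to the observations; (2) simulate
    ``n_past + n_future`` baseline years under ``seed``; (3) aggregate to N
    intervals; (4) apply the paleo anomaly to the historical years; (5)
    apply the scenario trajectory to the tail years; (6) compute PET from
    the fully modulated temperatures; (7) compute net rainfall.
    """
    cfg = config or PipelineConfig()
    cal = make_calendar(cfg.n_intervals)
    n_total = cfg.n_past_years + cfg.n_future_years
    if cfg.n_past_years < 1 or cfg.n_future_years < 0:
        raise ValidationError("need n_past_years >= 1 and n_future_years >= 0")

    log.info("stage fit: fitting weather generator (%d obs days)", obs.n_days)
    model = WeatherGenerator(wet_threshold_mm=cfg.wet_threshold_mm).fit(obs)

    log.info("stage generate: simulating %d baseline years (seed=%d)", n_total, seed)
    daily = model.sample(n_total, random_state=seed)

    log.info("stage aggregate: %d intervals per year", cfg.n_intervals)
    precip, temp = aggregate_daily(daily, cal)

    hist = slice(0, cfg.n_past_years)
    tail = slice(cfg.n_past_years, n_total)

    log.info("stage paleo: modulating years 1..%d", cfg.n_past_years)
    anomaly = select_grid_cell(site, anomaly_grid)
    dense = downscale_anomaly(anomaly, cfg.n_past_years, cfg.n_intervals)
    hist_p, hist_t = apply_paleo(
        SubAnnualSeries(precip.values[hist], "precip_total_mm"),
        SubAnnualSeries(temp.values[hist], "temp_mean_c"),
        dense,
        cal,
    )

    if cfg.n_future_years > 0:
        log.info("stage scenario: modulating %d tail years", cfg.n_future_years)
        traj = interpolate_scalers(scaler_sets, cfg.n_future_years)
        tail_p, tail_t = apply_scenario(
            SubAnnualSeries(precip.values[tail], "precip_total_mm"),
            SubAnnualSeries(temp.values[tail], "temp_mean_c"),
            traj,
        )
        full_p = np.vstack([hist_p.values, tail_p.values])
        full_t = np.vstack([hist_t.values, tail_t.values])
    else:
        full_p, full_t = hist_p.values, hist_t.values

    first_year = 2000 - cfg.n_past_years + 1
    precip_out = SubAnnualSeries(full_p, "precip_total_mm", epoch=first_year)
    temp_out = SubAnnualSeries(full_t, "temp_mean_c", epoch=first_year)

    log.info("stage pet: Thornthwaite PET and net rainfall")
    pet_out = pet_series(temp_out, site, cal)
    net_out = net_rainfall(precip_out, pet_out)

    return ClimateDriver(
        site=site,
        precip=precip_out,
        temp=temp_out,
        pet=pet_out,
        net=net_out,
        first_year=first_year,
        seed=seed,
        config=cfg.as_dict(),
    )
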