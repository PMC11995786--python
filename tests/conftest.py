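import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import peatclim as pc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def calendar12():
    return pc.make_calendar(12)


@pytest.fixture(scope="session")
def calendar52():
    return pc.make_calendar(52)


@pytest.fixture(scope="session")
def synth_params():
    return pc.SynthWeatherParams()


@pytest.fixture(scope="session")
def obs20(synth_params):
    """The 20-year synthetic observation fixture used throughout."""
    return pc.make_synthetic_obs(synth_params, n_years=20, seed=42)


@pytest.fixture(scope="session")
def fitted_model(obs20):
    return pc.fit_weathergen(obs20)


@pytest.fixture(scope="session")
def sim1000(fitted_model):
    """1000 simulated years from the generator fitted to the 20-year fixture."""
    return fitted_model.sample(1000, random_state=1)


@pytest.fixture(scope="session")
def site():
    return pc.SiteMeta("Altnaharra-like", lat=58.288, lon=-4.442, elevation_m=81)


def monthly_stats(daily, calendar, wet_threshold=0.1):
    """Empirical per-month wet-day frequency, mean wet amount and mean temp."""
    month = calendar.interval_of_day[np.arange(daily.n_days) % 365]
    wet = daily.precip_mm > wet_threshold
    tmean = daily.tmean_c
    freq = np.array([wet[month == m].mean() for m in range(12)])
    amount = np.array(
        [daily.precip_mm[wet & (month == m)].mean() if wet[month == m].any() else 0.0
         for m in range(12)]
    )
    temp = np.array([tmean[month == m].mean() for m in range(12)])
    return freq, amount, temp
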