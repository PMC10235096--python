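import numpy as np
import pandas as pd
import pytest

from oceanstations.synth import (FlowScenario, SstScenario, ThermalEvent,
                                 generate_sst_series, generate_velocity_field)


@pytest.fixture(scope="session")
def flat_sst():
    """Noise-free constant-climate series with one square heat wave."""
    scenario = SstScenario(start_date="2002-01-01", end_date="2016-12-31",
                           seasonal_amplitude=0.0, noise_sd=0.0,
                           events=[ThermalEvent("2015-04-01", 28, 2.0, "square")],
                           seed=1)
    return generate_sst_series(scenario)


@pytest.fixture(scope="session")
def noisy_sst():
    """20-year seasonal series with AR(1) noise, gaps and mixed events."""
    scenario = SstScenario(start_date="2002-01-01", end_date="2021-12-31",
                           seasonal_amplitude=2.0, noise_sd=0.3, ar1=0.3,
                           gap_fraction=0.05, gap_mean_len=5,
                           events=[ThermalEvent("2010-02-20", 21, 2.5, "square"),
                                   ThermalEvent("2016-08-05", 14, -2.0, "square")],
                           seed=7)
    return generate_sst_series(scenario)


@pytest.fixture(scope="session")
def solid_body_field():
    return generate_velocity_field(
        FlowScenario(kind="solid_body", params={"omega": 0.1},
                     lon_range=(-3, 3), lat_range=(-3, 3), n_days=70))


@pytest.fixture(scope="session")
def strain_field():
    return generate_velocity_field(
        FlowScenario(kind="strain", params={"sigma": 0.1},
                     lon_range=(-6, 6), lat_range=(-6, 6), n_days=70))


@pytest.fixture(scope="session")
def uniform_field():
    return generate_velocity_field(
        FlowScenario(kind="uniform", params={"u": 0.5},
                     lon_range=(-1, 6), lat_range=(-2, 2), n_days=70))


@pytest.fixture(scope="session")
def divergent_field():
    return generate_velocity_field(
        FlowScenario(kind="divergent", params={"delta": 0.05},
                     lon_range=(-2, 2), lat_range=(-2, 2), n_days=70))
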