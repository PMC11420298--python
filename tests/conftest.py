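import datetime as dt

import numpy as np
import pandas as pd
import pytest

from airmob.synthetic import (
    BackgroundModel,
    PlumeModel,
    RouteModel,
    ScenarioConfig,
    default_route,
    generate_scenario,
)


def seconds_index(n: int, start: str = "2021-05-17 07:00", tz: str = "UTC") -> pd.DatetimeIndex:
    return pd.date_range(start, periods=n, freq="1s", tz=tz)


@pytest.fixture(scope="session")
def small_scenario():
    """One monitored day, two pollutants, moderate plumes, no censoring."""
    cfg = ScenarioConfig(seed=11, n_days=1, pollutants=("PM2.5", "NO2"))
    bg = {
        "PM2.5": BackgroundModel(7.0, ((24, 2.0, 8.0),), ar1_coefficient=0.99, noise_sd=0.02),
        "NO2": BackgroundModel(14.0, ((24, 4.0, 8.0),), ar1_coefficient=0.99, noise_sd=0.04),
    }
    pm = {
        "PM2.5": PlumeModel(20.0, 1.2, 0.6, decay_seconds=30.0),
        "NO2": PlumeModel(30.0, 2.0, 0.6, decay_seconds=30.0),
    }
    obs, truth = generate_scenario(default_route(), bg, pm, cfg)
    return obs, truth


@pytest.fixture
def short_route():
    return RouteModel(
        waypoints=((53.35, -6.26), (53.35 + 100 / 111_195.0, -6.26)),
        speed_mps=10.0,
        session_windows=((dt.time(7, 0), dt.time(7, 0, 20)),),
    )


def constant_track(n: int) -> pd.DataFrame:
    """Stationary 'track' for plume tests where geometry is irrelevant."""
    idx = seconds_index(n)
    return pd.DataFrame({"lat": 53.35, "lon": -6.26}, index=idx)
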