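import numpy as np
import pandas as pd
import pytest

from medpql import popsim, weather


def make_constant_series(temp_c, n_days, start="2001-01-01"):
    n = n_days * 24
    return weather.HourlyTemperatureSeries(
        start=pd.Timestamp(start),
        temps=np.full(n, float(temp_c)),
        fill_flag=np.zeros(n, dtype=np.int8),
    )


def make_raw(times, temps):
    return weather.RawObservationSeries(times=pd.DatetimeIndex(times), temps=np.asarray(temps, float))


@pytest.fixture(scope="session")
def default_ranges():
    return popsim.default_ranges()


@pytest.fixture(scope="session")
def mid_latitude_params():
    """The documented study conditions for the synthetic mid-latitude climate."""
    return weather.SyntheticClimateParams(seed=20_001)


@pytest.fixture(scope="session")
def synthetic_two_years(mid_latitude_params):
    return weather.generate_synthetic_weather(mid_latitude_params, 2).series


@pytest.fixture
def fixed_vector(default_ranges):
    """A single mid-range parameter vector for deterministic-ish checks."""
    lo, hi = default_ranges.as_arrays()
    mid = (lo + hi) / 2.0
    return popsim.BioParamVector(
        values={n: float(v) for n, v in zip(popsim.PARAM_NAMES, mid)}
    )
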