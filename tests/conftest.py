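import datetime as dt

import numpy as np
import pandas as pd
import pytest

from wheatclim.weather import WeatherSeries
from wheatclim.synthetic import generate_series, preset


def build_series(start: dt.date, n_days: int, tmax=20.0, tmin=10.0, rain=0.0,
                 **meta) -> WeatherSeries:
    """Constant-or-vector daily series starting at *start*."""
    dates = pd.date_range(start, periods=n_days, freq="D")
    df = pd.DataFrame(
        {
            "date": dates,
            "tmax": np.broadcast_to(np.asarray(tmax, float), (n_days,)).copy(),
            "tmin": np.broadcast_to(np.asarray(tmin, float), (n_days,)).copy(),
            "rain": np.broadcast_to(np.asarray(rain, float), (n_days,)).copy(),
        }
    )
    meta.setdefault("site_id", "test")
    meta.setdefault("latitude", 33.0)
    meta.setdefault("longitude", 73.0)
    return WeatherSeries(df, **meta)


@pytest.fixture
def make_series():
    return build_series


@pytest.fixture(scope="session")
def islamabad_series():
    """One 41-season Islamabad-preset series, shared across tests."""
    return generate_series(preset("islamabad", seed=1))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
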