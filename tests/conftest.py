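import numpy as np
import pandas as pd
import pytest

from kelpwave import sst_metrics as sm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_series(start, end, values, zone_id="Z1"):
    dates = pd.date_range(start, end, freq="D")
    values = np.broadcast_to(np.asarray(values, dtype=float), (len(dates),)).copy()
    return sm.DailySstSeries(zone_id=zone_id, dates=dates, sst=values)


@pytest.fixture
def constant_series():
    """Three full years at exactly 10 °C."""
    return make_series("2001-01-01", "2003-12-31", 10.0)


@pytest.fixture
def toy_beta_data():
    """Fixed 12-point dataset for beta-regression oracle checks."""
    x = np.linspace(-1.5, 1.5, 12)
    y = np.array(
        [0.81, 0.72, 0.78, 0.64, 0.55, 0.62, 0.48, 0.35, 0.42, 0.27, 0.22, 0.18]
    )
    return y, x
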