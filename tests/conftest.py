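import numpy as np
import pandas as pd
import pytest

from streamtemp import lmm
from streamtemp.synthetic import TruthParams, simulate_paired_dataset


@pytest.fixture(scope="session")
def monthly_fit():
    """One converged monthly-scale REML fit, reused by metrics tests."""
    truth = TruthParams.monthly()
    sites, paired = simulate_paired_dataset(60, 10, truth, seed=11)
    spec = lmm.ModelSpec(correlation="none", method="REML")
    fitted = lmm.fit(paired, sites, spec)
    assert fitted.converged
    return fitted, paired, sites


@pytest.fixture(scope="session")
def daily_car_fit():
    """One converged daily-scale CAR(1) fit on a compact design."""
    truth = TruthParams.daily(phi=0.8)
    sites, paired = simulate_paired_dataset(25, 60, truth, seed=12)
    spec = lmm.ModelSpec(correlation="car1", method="REML")
    fitted = lmm.fit(paired, sites, spec)
    assert fitted.converged
    return fitted, paired, sites


def make_hourly_frame(values, start="2020-06-01", site_id="S001", air=None):
    """Hourly water series (optionally with air) from a plain value list;
    None entries become missing."""
    ts = pd.date_range(start, periods=len(values), freq="h")
    water = np.array([np.nan if v is None else float(v) for v in values])
    frame = pd.DataFrame({"timestamp": ts, "air": np.nan if air is None else air, "water": water})
    frame.attrs["site_id"] = site_id
    return frame
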