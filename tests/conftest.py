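import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from bootmi import Dataset

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20200630)


@pytest.fixture
def linear_data(rng):
    """Complete data with y = 1 + 2x + 0.5g + noise and a binary group g."""
    n = 120
    x = rng.normal(0.0, 1.0, n)
    g = (rng.random(n) < 0.5).astype(float)
    y = 1.0 + 2.0 * x + 0.5 * g + rng.normal(0.0, 0.7, n)
    return Dataset(pd.DataFrame({"x": x, "g": g, "y": y}))


@pytest.fixture
def incomplete_trial(rng):
    """A small two-arm trial table with ~40% of outcomes missing."""
    n = 200
    z = np.repeat([0.0, 1.0], n // 2)
    x = rng.normal(2.0, 0.6, n)
    y = 2.0 + 0.2 * z + 0.5 * (x - 2.0) + rng.normal(0.0, 0.55, n)
    y = np.where(rng.random(n) < 0.4, np.nan, y)
    return Dataset(pd.DataFrame({"x": x, "y": y, "z": z}))
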