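import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from trajperm import default_catalog
from trajperm.trend import ScoreSeries

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


def make_series(values, codes=None, name="TEST"):
    """Build a ScoreSeries from a nested list grid (None = missing)."""
    grid = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in values]
    )
    n_t = grid.shape[1]
    codes = np.arange(n_t, dtype=float) if codes is None else np.asarray(codes, float)
    participants = tuple(f"P{i}" for i in range(grid.shape[0]))
    timepoints = tuple(f"pre post m1 m3 m6".split()[:n_t])
    return ScoreSeries(name, participants, timepoints, codes, grid)


@pytest.fixture
def series_factory():
    return make_series
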