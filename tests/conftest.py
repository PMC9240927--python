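import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from graftsurv import TimeGrid

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return TimeGrid()


@pytest.fixture(scope="session")
def small_grid():
    """A 5-interval annual grid for cheap exact examples."""
    return TimeGrid(horizon_years=5.0, step_years=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
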