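import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ssbimpact.strata import BaselineTable, stratum_grid
from ssbimpact.synthetic import load_fixture

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def paper_baseline() -> BaselineTable:
    """The default calibrated synthetic baseline (38k deaths, 99.5 g/d)."""
    return load_fixture("paper-calibrated")


@pytest.fixture(scope="session")
def degenerate_baseline() -> BaselineTable:
    """Uniform round-number baseline for hand arithmetic."""
    return load_fixture("degenerate")


def random_baseline(seed: int) -> BaselineTable:
    """A structurally valid baseline with random values (no gradients)."""
    rng = np.random.default_rng(seed)
    grid = stratum_grid()
    n = len(grid)
    df = grid.copy()
    df["deaths"] = rng.uniform(0, 2000, n)
    df["population"] = rng.uniform(1e4, 1e6, n)
    df["intake"] = rng.uniform(5, 250, n)
    df["overweight_prevalence"] = rng.uniform(0.0, 1.0, n)
    props = rng.dirichlet(np.ones(3), size=n)
    df["p_diagnosed_chd"] = props[:, 0]
    df["p_undiagnosed_chd"] = props[:, 1]
    df["p_no_chd"] = 1.0 - props[:, 0] - props[:, 1]
    df["survival_diagnosed_chd"] = rng.uniform(0.5, 20, n)
    df["survival_undiagnosed_chd"] = rng.uniform(0.5, 25, n)
    df["survival_no_chd"] = rng.uniform(1, 50, n)
    return BaselineTable(df)


@pytest.fixture(params=[0, 1, 2])
def any_baseline(request) -> BaselineTable:
    return random_baseline(request.param)
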