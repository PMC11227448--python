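import numpy as np
import pytest

from lueff import ScenarioConfig, generate_scenario
from lueff.dea import DEAProblem


@pytest.fixture(scope="session")
def small_landscape():
    """12 x 12 km synthetic landscape (144 LUs), shared across tests."""
    return generate_scenario(ScenarioConfig(n_rows=12, n_cols=12, seed=7))


@pytest.fixture(scope="session")
def large_landscape():
    """45 x 45 km landscape (2025 LUs) for Monte-Carlo marginal checks."""
    return generate_scenario(ScenarioConfig(n_rows=45, n_cols=45, seed=5))


@pytest.fixture
def toy_problem():
    """Three DMUs with unit input and outputs A=(2,1), B=(1,2), C=(1,1);
    hand-solved scores are (1, 1, 2/3)."""
    return DEAProblem(
        x=np.ones((3, 1)),
        y=np.array([[2.0, 1.0], [1.0, 2.0], [1.0, 1.0]]),
        dmu_names=["A", "B", "C"],
    )


def random_single_input_problem(rng, n_max=8, s_max=3):
    n = int(rng.integers(1, n_max + 1))
    s = int(rng.integers(1, s_max + 1))
    return DEAProblem(
        x=rng.uniform(0.001, 100, (n, 1)), y=rng.uniform(0.001, 100, (n, s))
    )
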