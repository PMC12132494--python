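import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_sample(rng):
    """Small unstructured sample: n=60, p=3 responses, one covariate."""
    from covfun import GroupSample

    n = 60
    U = rng.uniform(-1, 1, n)
    X = rng.standard_normal((n, 3)) + 0.5 * U[:, None]
    return GroupSample(X=X, Ucont=U)


@pytest.fixture(scope="session")
def groups_1d():
    """A simulated pair from the 1-D design: theta = 0.5 vs 1.0, n=400."""
    from covfun import simlab

    g0 = simlab.simulate_group_1d(400, 0.5, seed=11)
    g1 = simlab.simulate_group_1d(400, 1.0, seed=12)
    return g0, g1


@pytest.fixture(scope="session")
def null_groups_1d():
    """A simulated null pair (both theta = 0.5), n=400."""
    from covfun import simlab

    g0 = simlab.simulate_group_1d(400, 0.5, seed=21)
    g1 = simlab.simulate_group_1d(400, 0.5, seed=22)
    return g0, g1
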