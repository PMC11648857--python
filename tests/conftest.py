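import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import trophicstab as ts
from trophicstab._rng import child_rng

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240919)


@pytest.fixture
def small_community():
    """A quick, stable 8-predator / 16-prey community with yield variation."""
    spec = ts.EnsembleSpec(N=8, M=16, sigma_Y=0.3, seed=7)
    return ts.sample_community(spec, child_rng(spec.seed))


@pytest.fixture
def unit_community():
    """The 1-predator / 1-prey worked example: C=0.5, Y=0.3, S*=R*=1, g=1."""
    C = np.array([[0.5]])
    Y = np.array([[0.3]])
    eps = np.zeros(1)
    S = np.ones(1)
    R = np.ones(1)
    g = np.ones(1)
    delta, K, _ = ts.solve_consistent_parameters(C, Y, None, None, eps, S, R, "logistic", g)
    return ts.Community(
        C=C, Y=Y, delta=delta, epsilon=eps, supply_model="logistic",
        supply_g=g, supply_K=K, S_star=S, R_star=R,
    )
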