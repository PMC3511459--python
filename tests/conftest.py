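import numpy as np
import pytest

from circmove.simulate import make_fixture, simulate_trajectory
from circmove.trajectory import derive_steps


@pytest.fixture(scope="session")
def oriented_series():
    """A 2000-step series from the steadily oriented scenario (known truth:
    alpha=0, w=0.5, kappa=6)."""
    sc = make_fixture("oriented", seed=101)
    return derive_steps(simulate_trajectory(sc), 1.0), sc


@pytest.fixture(scope="session")
def wind_skewed_series():
    """A 2000-step series from the wind-skewed Kato-Jones scenario (truth:
    alpha=-pi/8, w=0.7, kappa=6, r=0.3, lambda=5pi/8)."""
    sc = make_fixture("wind_skewed", seed=202)
    return derive_steps(simulate_trajectory(sc), 1.0), sc


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
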