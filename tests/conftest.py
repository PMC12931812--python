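import numpy as np
import pytest

from damagepde.model_core import DeathModel, DediffRule, FeedbackParams, ModelParams, make_grid


@pytest.fixture
def grid():
    """Default production grid on [0, 2] with dx = 0.005."""
    return make_grid(2.0, 400)


@pytest.fixture
def coarse_grid():
    return make_grid(2.0, 100)


@pytest.fixture
def rng():
    return np.random.default_rng(20260212)


@pytest.fixture
def random_density(grid, rng):
    """A nonnegative density vanishing at both domain ends."""
    u = rng.random(grid.size)
    u[0] = u[-1] = 0.0
    return u


@pytest.fixture
def conservation_params():
    """Symmetric division, all sinks off: the exact-conservation setting."""
    return ModelParams(
        v_P=0.0,
        v_W=0.0,
        feedback=FeedbackParams(p1_hat=0.5, p2_hat=0.5, lam_P_hat=1.0, lam_R_hat=0.0),
        death=DeathModel("constant", 0.0),
        dediff=DediffRule("constant"),
    )
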