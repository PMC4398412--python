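import numpy as np
import pytest

from creolang import ModelParams, TransitionStripe, build_stripe


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def paper_params():
    """The headline parameter set: gamma=0.8, delta=0.1, epsilon=0.06."""
    return ModelParams(gamma=0.8, delta=0.1, epsilon=0.06, seed=0)


@pytest.fixture(scope="session")
def small_stripe():
    """A desk-scale transition stripe computed once per session.

    Small population and coarse tolerance keep it cheap; it is a real
    stripe (three simulated transition curves), not a hand-drawn one.
    """
    params = ModelParams(gamma=0.8, delta=0.1, epsilon=0.06, seed=11)
    return build_stripe(
        params,
        xs=[0.02, 0.08, 0.25],
        n_total=600,
        n_replicates=5,
        y_tolerance=0.05,
        seed=11,
    )


@pytest.fixture
def toy_stripe():
    """Hand-built stripe with known geometry for classifier unit tests."""
    xs = np.array([0.0, 0.5, 1.0])
    return TransitionStripe(
        xs=xs,
        y_lower=np.array([0.4, 0.5, 0.6]),
        y_mid=np.array([0.45, 0.55, 0.65]),
        y_upper=np.array([0.5, 0.6, 0.7]),
    )
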