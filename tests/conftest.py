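import numpy as np
import pytest

from articuvel.synthetic import PhantomSpec, make_trajectory


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def default_truth(default_spec):
    return make_trajectory(default_spec)


@pytest.fixture(scope="session")
def tiny_spec():
    """Small, noise-free phantom for fast unit tests."""
    return PhantomSpec(n_cycles=1, image_shape=(32, 32), fov=160.0,
                       frame_interval_rt=0.04, noise_sd=0.0,
                       motion_blur=False, seed=7)


@pytest.fixture(scope="session")
def tiny_truth(tiny_spec):
    return make_trajectory(tiny_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
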