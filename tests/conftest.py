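import numpy as np
import pytest

from grouptemplate.core_io import Volume
from grouptemplate.synthetic import PhantomSpec, make_mean_brain, make_subject


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """Small, quiet phantom for module-level tests."""
    return PhantomSpec(grid_shape=(48, 48, 24), noise_sd=0.0, seed=5)


@pytest.fixture(scope="session")
def small_brain(small_spec):
    return make_mean_brain(small_spec)


@pytest.fixture(scope="session")
def noisy_spec():
    """Mid-size phantom at the generator's default noise level."""
    return PhantomSpec(grid_shape=(64, 64, 32), seed=3)


@pytest.fixture(scope="session")
def noisy_brain(noisy_spec):
    return make_mean_brain(noisy_spec)


@pytest.fixture(scope="session")
def noisy_subject(noisy_brain, noisy_spec):
    return make_subject(noisy_brain, noisy_spec, seed=42)


@pytest.fixture()
def random_volume(rng):
    return Volume(rng.random((16, 16, 16)), (1.0, 1.0, 2.0), (0.0, -3.0, 5.0))
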