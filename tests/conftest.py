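import numpy as np
import pytest

from ivdquant import PhantomSpec, generate_phantom, phantom_contours
from ivdquant.cli import PipelineConfig


@pytest.fixture(scope="session")
def small_spec():
    """Noiseless phantom at reduced lattice size for fast unit tests."""
    return PhantomSpec(shape=(80, 96, 96), disc_radius_um=400.0,
                       vertebra_radius_um=400.0, noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def small_contours(small_spec):
    return phantom_contours(small_spec)


@pytest.fixture(scope="session")
def fast_config():
    """Pipeline config with a smaller filter radius for quick tests."""
    return PipelineConfig(filter_radius=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
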