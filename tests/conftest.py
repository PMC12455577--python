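import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from cestpipe.spectra import (
    default_cest_schedule,
    default_pools,
    default_wassr_schedule,
)
from cestpipe.synthetic import PhantomConfig, generate_phantom_study


@pytest.fixture(scope="session")
def cest_schedule():
    return default_cest_schedule()


@pytest.fixture(scope="session")
def wassr_schedule():
    return default_wassr_schedule()


@pytest.fixture(scope="session")
def pools():
    return default_pools()


@pytest.fixture(scope="session")
def small_noiseless_bundle():
    """16-subject study on a small grid, no noise, no B0 field."""
    config = PhantomConfig(grid_shape=(16, 16), noise_sd=0.0, b0_amplitude_ppm=0.0)
    return generate_phantom_study(config)


@pytest.fixture(scope="session")
def small_noisy_bundle():
    config = PhantomConfig(grid_shape=(16, 16), seed=3)
    return generate_phantom_study(config)
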