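import numpy as np
import pytest
from hypothesis import settings

import clutraffic as ct
from clutraffic.scenes import NoiseParams, make_scene

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

ZERO_NOISE = NoiseParams(background_level=100.0, background_sd=0.0, shot_scale=0.0)


@pytest.fixture(scope="session")
def flpin():
    return ct.flpin_phenotypes()


@pytest.fixture(scope="session")
def default_scene(flpin):
    """One field with all three Flp-In phenotypes under default noise."""
    return make_scene(12, list(flpin.values()), image_shape=(420, 420), seed=11)


@pytest.fixture(scope="session")
def noiseless_scene(flpin):
    return make_scene(
        6, list(flpin.values()), image_shape=(360, 360), noise=ZERO_NOISE, seed=5
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
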