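import numpy as np
import pytest

from fundus_shift import (Image, PreprocessConfig, SyntheticImageParams,
                          synth_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def flat_image():
    """8x8 flat mid-gray image with all-true mask."""
    return Image(pixels=np.full((8, 8, 3), 0.5))


@pytest.fixture
def random_image(rng):
    return Image(pixels=rng.uniform(size=(8, 8, 3)))


@pytest.fixture(scope="session")
def fast_preprocess():
    """Native-resolution raster keeps unit tests quick; contracts are size-free."""
    return PreprocessConfig(target_size=128)


@pytest.fixture(scope="session")
def small_synth_dataset():
    """120 synthetic fundus images, 35% positive, shared across tests."""
    params = SyntheticImageParams(seed=77)
    return synth_dataset(params, 120, 0.35, np.random.default_rng(77))
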