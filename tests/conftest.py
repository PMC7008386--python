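import numpy as np
import pytest

from hsmcr.io_cube import SpectralImage
from hsmcr.synthetic import SceneParams, simulate_multiset


@pytest.fixture
def axis276():
    return np.arange(1200.0, 1750.0 + 1e-9, 2.0)


@pytest.fixture
def small_image(axis276):
    rng = np.random.default_rng(7)
    cube = np.abs(rng.normal(0.3, 0.1, size=(4, 5, axis276.size)))
    return SpectralImage(cube=cube, axis=axis276, meta={"section_id": "X1"})


@pytest.fixture(scope="session")
def clean_scene():
    """Noiseless, baseline-free default scene (shared, treat as read-only)."""
    params = SceneParams(seed=1)
    images, truth = simulate_multiset(params)
    return params, images, truth


@pytest.fixture(scope="session")
def small_scene():
    """Tiny 3-component noiseless scene for fast decomposition tests."""
    params = SceneParams(
        n_images=4,
        image_shape=(16, 16),
        n_components=3,
        profiles=("cellulose", "lignin_sw", "extractives"),
        presence=np.ones((4, 3), dtype=bool),
        seed=1,
    )
    images, truth = simulate_multiset(params)
    return params, images, truth
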