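import numpy as np
import pytest

from synquant.models import ThresholdKeypointModel, ThresholdSegmenter
from synquant.synthgen import SceneParams, generate_stack


@pytest.fixture(scope="session")
def noiseless_params() -> SceneParams:
    """Clean scene: no noise, no impurities, full boundary contrast."""
    return SceneParams(
        image_height=192,
        image_width=192,
        n_z=5,
        focal_z=2,
        n_cells=5,
        noise_sigma=0.0,
        shot_noise=False,
        impurity_density=0.0,
        boundary_contrast=1.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def noiseless_scene(noiseless_params):
    return generate_stack(noiseless_params)


@pytest.fixture(scope="session")
def noisy_scene():
    params = SceneParams(n_cells=8, seed=5)
    return generate_stack(params)


@pytest.fixture(scope="session")
def oracle_models():
    return ThresholdKeypointModel(), ThresholdSegmenter()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_blob_mask(rng, shape=(48, 48), r=10) -> np.ndarray:
    """Irregular simply-connected test mask."""
    from scipy import ndimage

    h, w = shape
    m = np.zeros(shape, bool)
    cy, cx = h // 2 + rng.integers(-5, 6), w // 2 + rng.integers(-5, 6)
    yy, xx = np.mgrid[:h, :w]
    ang = np.arctan2(yy - cy, xx - cx)
    rad = r * (1 + 0.25 * np.cos(2 * ang + rng.uniform(0, 6)) + 0.15 * np.sin(3 * ang))
    m = np.hypot(yy - cy, xx - cx) <= rad
    return ndimage.binary_fill_holes(m)
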