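import numpy as np
import pytest

from fundusma.config import RunConfig
from fundusma.synthetic import SceneSpec, generate_scene


def small_spec(**overrides) -> SceneSpec:
    """A reduced scene that still exercises every pipeline stage."""
    base = dict(shape=(320, 320), fov_radius=140, n_vessels=4,
                vessel_width_range=(6.0, 12.0), n_ma=8,
                ma_contrast_range=(0.3, 0.45), n_hemorrhage=1,
                hemorrhage_area_range=(700.0, 1200.0), seed=5)
    base.update(overrides)
    return SceneSpec(**base)


@pytest.fixture(scope="session")
def small_scene():
    return generate_scene(small_spec())


@pytest.fixture(scope="session")
def small_planes(small_scene):
    from fundusma.preprocess import preprocess_image

    img, _ = small_scene
    return preprocess_image(img)


@pytest.fixture(scope="session")
def small_result(small_scene):
    from fundusma.pipeline import process_image

    img, _ = small_scene
    return process_image(img, RunConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def disk_mask(shape, center, radius):
    rr, cc = np.ogrid[:shape[0], :shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2
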