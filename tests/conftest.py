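import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from uavweed.mission import MULTISPECTRAL_CAMERA
from uavweed.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def ms_camera():
    """Six-band multispectral camera from the published rig."""
    return MULTISPECTRAL_CAMERA


@pytest.fixture(scope="session")
def small_scene():
    """8 x 8 m sub-scene at 5 cm GSD: fast, with panel + frames + crop rows."""
    cfg = SceneConfig(field_size=(8.0, 8.0), gsd=5.0, n_frames=4,
                      weed_patch_density=600.0, seed=1)
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def recovery_scene():
    """10 x 10 m sub-scene used for parameter-recovery checks."""
    cfg = SceneConfig(field_size=(10.0, 10.0), gsd=5.0, n_frames=1,
                      weed_patch_density=400.0, seed=0)
    return generate_scene(cfg)


@pytest.fixture()
def smooth_image():
    """A smooth non-constant test image with broad spatial structure."""
    from scipy import ndimage

    rng = np.random.default_rng(0)
    img = ndimage.gaussian_filter(rng.normal(size=(128, 128)), 3.0)
    return 100.0 + 50.0 * img / np.abs(img).max()
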