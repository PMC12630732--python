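import numpy as np
import pytest

from stabilock import default_config
from stabilock.simscope import CameraModel, FiducialField, FocusBeamModel


@pytest.fixture
def quiet_config():
    """Default scenario with all noise and drift switched off."""
    cfg = default_config()
    cfg.drift.velocity[:] = 0.0
    cfg.drift.diffusion[:] = 0.0
    cfg.camera.shot_noise = False
    cfg.camera.read_noise_sigma = 0.0
    return cfg


@pytest.fixture
def default_cfg():
    return default_config()


@pytest.fixture
def small_scene():
    """A compact 64x64 scene with four fiducials and a central focus spot."""
    camera = CameraModel(
        pixel_size_nm=80.0, shape=(64, 64), baseline=0.0, read_noise_sigma=0.0, shot_noise=True
    )
    field = FiducialField(
        positions_nm=np.array([[16, 16], [16, 48], [48, 16], [48, 48]], float) * 80.0,
        spot_sigma_nm=184.0,
        photons_per_frame=5000.0,
    )
    focus = FocusBeamModel(base_position_nm=[32 * 80.0, 32 * 80.0], photons_per_frame=1e5)
    return field, focus, camera
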