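import numpy as np
import pytest

from glottimetry import (
    BreathingKinematics,
    GlottisShape,
    SceneParams,
)


@pytest.fixture
def default_shape():
    return GlottisShape()


@pytest.fixture
def default_kin():
    return BreathingKinematics()


@pytest.fixture
def default_scene():
    return SceneParams()


@pytest.fixture
def noiseless_scene():
    return SceneParams(noise_sd=0.0, illum_gradient=0.0)


@pytest.fixture
def small_shape():
    """A downscaled glottis for fast rendered tests."""
    return GlottisShape(length_px=60.0, halfwidth_px=15.0,
                        center_rowcol=(64.0, 64.0))


@pytest.fixture
def small_scene():
    return SceneParams(image_size_rowcol=(128, 128))


def ellipse_mask(a: float, b: float, size: int | None = None,
                 angle_deg: float = 0.0) -> np.ndarray:
    """Pixel-center rasterized ellipse with semi-axes a (cols) and b (rows)."""
    if size is None:
        size = int(2 * max(a, b) + 21)
    c0 = (size - 1) / 2
    rr, cc = np.mgrid[0:size, 0:size]
    dr, dc = rr - c0, cc - c0
    t = np.deg2rad(angle_deg)
    x = dc * np.cos(t) + dr * np.sin(t)
    y = -dc * np.sin(t) + dr * np.cos(t)
    return (x / a) ** 2 + (y / b) ** 2 <= 1.0
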