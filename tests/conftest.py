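import numpy as np
import pytest

from dcrmotion import AcquisitionGeometry, MotionPattern, project_and_sample, render_video


@pytest.fixture(scope="session")
def small_geom():
    """Compact detector geometry keeping renders fast in unit tests."""
    return AcquisitionGeometry(matrix_px=256)


@pytest.fixture(scope="session")
def short_geom():
    """A 4-second acquisition (60 frames) on the compact detector."""
    return AcquisitionGeometry(matrix_px=256, duration_s=4.0)


@pytest.fixture(scope="session")
def vertical_pattern():
    return MotionPattern(amplitude_mm=20.0, period_s=4.0, magnification=1.20)


@pytest.fixture(scope="session")
def rendered_vertical(small_geom, vertical_pattern):
    """Noisy 20 mm / 4 s vertical-motion video with its ground truth."""
    truth = project_and_sample(vertical_pattern, small_geom)
    stack = render_video(truth, small_geom, noise_sd=240.0, seed=7)
    return stack, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
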