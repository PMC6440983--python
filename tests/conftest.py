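import numpy as np
import pytest

from mousetrack import synthetic
from mousetrack.augmentation import TrainingSample
from mousetrack.geometry import EllipseFit, quadrant_of_angle


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """High-contrast 96 px arena used across tests."""
    return synthetic.preset("black", frame_size=96)


@pytest.fixture(scope="session")
def rendered_sample(small_scene):
    """One deterministic rendered sample with exact ground truth."""
    rng = np.random.default_rng(7)
    pose = synthetic.sample_pose(small_scene, rng)
    frame, mask, ell = synthetic.render_frame(pose, small_scene, rng)
    return TrainingSample(frame=frame, mask=mask, ellipse=ell,
                          direction=quadrant_of_angle(ell.theta_deg),
                          sample_id="fix0")


def random_ellipse(rng, frame_size, min_minor=8.0):
    """A random mouse-like ellipse (aspect 0.3-0.6) fully inside the frame."""
    lo = min_minor / 0.55
    hi = max(0.3 * frame_size, lo * 1.2)
    major = rng.uniform(lo, hi)
    minor = rng.uniform(max(0.3 * major, min_minor), 0.6 * major)
    margin = major / 2.0 + 1.0
    return EllipseFit.from_angle(
        x=rng.uniform(margin, frame_size - 1 - margin),
        y=rng.uniform(margin, frame_size - 1 - margin),
        major=major, minor=minor, theta_deg=rng.uniform(0, 360))
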