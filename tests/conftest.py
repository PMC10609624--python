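import numpy as np
import pytest

from dropsizer.detect import CircleDetection
from dropsizer.synthgen import (SceneRanges, SceneSpec, generate_image,
                                random_scene)

# Scene conditions used across the suite.  High contrast emulates
# refractive-index-mismatched phases (strong interface shadow); low contrast
# emulates the index-matched regime where the interface is barely visible.
HIGH_CONTRAST = dict(interface_contrast=0.8, sensor_noise_sigma=1.0)
LOW_CONTRAST = dict(interface_contrast=0.12, sensor_noise_sigma=2.0)
CHAIN_CONTRAST = dict(interface_contrast=0.2, sensor_noise_sigma=2.0)


def make_scenes(n, seed, diameter_um=(160.0, 330.0), **scene_kw):
    """Generate n random scenes; returns [(DropletImage, [GroundTruthCircle])]."""
    rng = np.random.default_rng(seed)
    template = SceneSpec(**scene_kw)
    ranges = SceneRanges(diameter_um=diameter_um)
    return [generate_image(random_scene(template, rng, ranges)) for _ in range(n)]


def gt_detections(circles):
    """Ground-truth circles as a detection list (the oracle reference)."""
    return [
        CircleDetection(c.center_x_px, c.center_y_px, c.diameter_px,
                        c.diameter_um, 1.0)
        for c in circles
    ]


@pytest.fixture(scope="session")
def high_contrast_scene():
    img, gt = make_scenes(1, seed=42, **HIGH_CONTRAST)[0]
    return img, gt
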