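import numpy as np
import pytest

from conftest import HIGH_CONTRAST, gt_detections
from dropsizer.detect import (CapabilityError, DetectorParams,
                              GroundTruthBackend, IntensityBackend,
                              detect_cht, detect_sam_cht, get_backend,
                              mask_to_circles, segment_auto)
from dropsizer.metrics import dice, match_detections
from dropsizer.synthgen import (DropletImage, SceneSpec, generate_image,
                                ground_truth_mask, rasterize_disk)

BLANK = DropletImage(np.full((288, 928), 200.0, np.float32), 1.25)


class TestCht:
    def test_blank_image_empty(self):
        assert detect_cht(BLANK) == []

    def test_single_ring_recovered(self, high_contrast_scene):
        img, gt = high_contrast_scene
        dets = detect_cht(img)
        m = match_detections(gt_detections(gt), dets)
        assert len(m.pairs) == len(gt)
        for i, j, d in m.pairs:
            assert d <= 2.0
            assert dets[j].diameter_px == pytest.approx(gt[i].diameter_px, rel=0.02)

    def test_below_minimum_diameter_rejected(self):
        # an 80 um droplet is outside the 130-390 um admissible window
        img, _ = generate_image(
            SceneSpec(droplets=((400, 144, 80.0),), **HIGH_CONTRAST, seed=1))
        assert detect_cht(img) == []

    def test_nms_contract(self, high_contrast_scene):
        img, _ = high_contrast_scene
        dets = detect_cht(img)
        for i, a in enumerate(dets):
            for b in dets[i + 1:]:
                d = np.hypot(a.center_x_px - b.center_x_px,
                             a.center_y_px - b.center_y_px)
                assert d >= 0.5 * min(a.radius_px, b.radius_px)

    def test_unusable_radius_range_rejected(self):
        img = DropletImage(np.zeros((32, 32), np.float32), 100.0)
        with pytest.raises(ValueError):
            detect_cht(img)  # bounds map to < 2 px radius


class TestBackends:
    def test_unknown_backend_is_capability_error(self):
        with pytest.raises(CapabilityError):
            get_backend("does-not-exist")

    def test_sam_backend_unavailable_is_explicit(self):
        with pytest.raises(CapabilityError):
            get_backend("sam", checkpoint="/nonexistent.pth")

    def test_blank_image_no_masks(self):
        assert segment_auto(BLANK, IntensityBackend()) == []

    def test_intensity_masks_match_ground_truth(self, high_contrast_scene):
        img, gt = high_contrast_scene
        masks = segment_auto(img, IntensityBackend())
        gt_masks = ground_truth_mask(gt, img.shape)
        assert len(masks) == len(gt)
        for gm in gt_masks:
            assert max(dice(gm, m) for m in masks) >= 0.9

    def test_area_filter_drops_tiny_masks(self, high_contrast_scene):
        img, _ = high_contrast_scene

        class Tiny:
            def segment(self, image):
                m = np.zeros(image.shape, bool)
                m[10:13, 10:13] = True
                return [(m, 1.0)]

        assert segment_auto(img, Tiny()) == []


class TestMaskToCircles:
    def test_perfect_disk(self):
        mask = rasterize_disk((300, 928), 400, 150, 100)
        (det,) = mask_to_circles([mask], DetectorParams(), 1.25)
        assert det.diameter_px == pytest.approx(200, abs=1.0)
        assert det.diameter_um == pytest.approx(det.diameter_px * 1.25)

    def test_empty_list(self):
        assert mask_to_circles([], DetectorParams(), 1.25) == []

    def test_two_disjoint_disks(self):
        m1 = rasterize_disk((300, 928), 200, 150, 80)
        m2 = rasterize_disk((300, 928), 600, 150, 110)
        dets = mask_to_circles([m1, m2], DetectorParams(), 1.25)
        got = sorted(d.diameter_px for d in dets)
        assert got == pytest.approx([160, 220], abs=1.0)

    def test_scale_equivariance(self):
        mask = rasterize_disk((300, 300), 150, 150, 80)
        params2 = DetectorParams(min_diameter_um=130, max_diameter_um=780)
        (d1,) = mask_to_circles([mask], DetectorParams(), 1.25)
        big = np.kron(mask, np.ones((2, 2), bool))
        (d2,) = mask_to_circles([big], params2, 1.25)
        assert d2.diameter_px == pytest.approx(2 * d1.diameter_px, abs=1.0)


class TestSamCht:
    def test_ground_truth_backend_roundtrip(self, high_contrast_scene):
        img, gt = high_contrast_scene
        dets = detect_sam_cht(img, GroundTruthBackend(gt))
        m = match_detections(gt_detections(gt), dets)
        assert len(m.pairs) == len(gt)
        for i, j, _ in m.pairs:
            assert dets[j].diameter_px == pytest.approx(gt[i].diameter_px, abs=1.0)

    def test_blank_image_empty(self):
        assert detect_sam_cht(BLANK, IntensityBackend()) == []
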