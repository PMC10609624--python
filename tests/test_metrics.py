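import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dropsizer.detect import CircleDetection
from dropsizer.metrics import (aggregate_records, dice, evaluate_detections,
                               iou, match_detections, psnr, ssim)
from dropsizer.synthgen import DropletImage


def _mask_pair(seed, shape=(16, 16), p=0.3):
    rng = np.random.default_rng(seed)
    return rng.random(shape) < p, rng.random(shape) < p


class TestOverlap:
    def test_identical_and_disjoint(self):
        a = np.zeros((8, 8), bool)
        a[2:5, 2:5] = True
        b = np.zeros((8, 8), bool)
        b[6:8, 6:8] = True
        assert dice(a, a) == 1.0 and iou(a, a) == 1.0
        assert dice(a, b) == 0.0 and iou(a, b) == 0.0

    def test_hand_counted_overlap(self):
        a = np.zeros((4, 4), bool); a[0, :4] = True
        b = np.zeros((4, 4), bool); b[0, 2:4] = True; b[1, 0:2] = True
        # |A|=|B|=4, |A∩B|=2
        assert dice(a, b) == pytest.approx(0.5)
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_both_empty_convention(self):
        e = np.zeros((4, 4), bool)
        assert dice(e, e) == 1.0 and iou(e, e) == 1.0

    def test_dim_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.zeros((3, 3), bool), np.zeros((4, 4), bool))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_iou_dice_identity(self, seed):
        a, b = _mask_pair(seed)
        d, j = dice(a, b), iou(a, b)
        assert 0.0 <= j <= d <= 1.0
        assert j == pytest.approx(d / (2 - d), abs=1e-12)


class TestPsnrSsim:
    def test_identical_gives_sentinel_and_one(self):
        img = DropletImage(np.random.default_rng(0).uniform(0, 255, (32, 32))
                           .astype(np.float32), 1.25)
        assert psnr(img, img) == math.inf
        assert ssim(img, img) == pytest.approx(1.0, abs=1e-7)

    def test_uniform_error_closed_form(self):
        a = np.full((50, 50), 100.0)
        assert psnr(a, a + 5.0) == pytest.approx(10 * np.log10(255**2 / 25), abs=1e-9)
        # halving the MSE raises PSNR by 3.0103 dB
        quarter = psnr(a, a + 5.0 / np.sqrt(2))
        assert quarter - psnr(a, a + 5.0) == pytest.approx(10 * np.log10(2), abs=1e-6)

    def test_ssim_drops_under_strong_noise(self):
        rng = np.random.default_rng(3)
        ref = np.full((128, 128), 128.0)
        noisy = ref + rng.normal(0, 50, ref.shape)
        assert ssim(ref, noisy) < 0.5

    def test_ssim_symmetric(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 255, (40, 40))
        b = rng.uniform(0, 255, (40, 40))
        assert ssim(a, b) == pytest.approx(ssim(b, a), abs=1e-12)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((8, 8)), np.zeros((8, 8)))


def _det(x, y, d_um, um_per_px=1.25):
    return CircleDetection(x, y, d_um / um_per_px, d_um, 1.0)


class TestMatching:
    def test_identical_sets_all_paired(self):
        ref = [_det(100, 100, 200), _det(300, 100, 180)]
        m = match_detections(ref, list(ref))
        assert len(m.pairs) == 2 and not m.unmatched_ref and not m.unmatched_test
        assert all(d == 0 for _, _, d in m.pairs)

    def test_empty_test(self):
        m = match_detections([_det(1, 1, 200)], [])
        assert m.unmatched_ref == [0] and not m.pairs

    def test_nearest_neighbour_by_hand(self):
        ref = [_det(100, 100, 100), _det(300, 100, 100)]
        test = [_det(104, 100, 100)]
        m = match_detections(ref, test)
        assert m.pairs == [(0, 0, pytest.approx(4.0))]
        assert m.unmatched_ref == [1]

    def test_gate_rejects_distant(self):
        ref = [_det(100, 100, 100)]  # radius 40 px -> gate 20 px
        m = match_detections(ref, [_det(130, 100, 100)])
        assert not m.pairs

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matching_one_to_one(self, seed):
        rng = np.random.default_rng(seed)
        ref = [_det(*rng.uniform(0, 500, 2), rng.uniform(140, 330)) for _ in range(5)]
        test = [_det(*rng.uniform(0, 500, 2), rng.uniform(140, 330)) for _ in range(5)]
        m = match_detections(ref, test)
        ri = [i for i, _, _ in m.pairs]
        ti = [j for _, j, _ in m.pairs]
        assert len(set(ri)) == len(ri) and len(set(ti)) == len(ti)


class TestEvaluate:
    def test_fixed_point(self):
        ref = [_det(100, 100, 200), _det(400, 150, 300)]
        rec = evaluate_detections(ref, list(ref), 1.25, (288, 928))
        assert rec.pct_detection == 1.0
        assert rec.droplets_abs_err_um == 0.0
        assert rec.detections_abs_err_um == 0.0
        assert rec.dice == 1.0 and rec.iou == 1.0

    def test_two_tier_error_hand_example(self):
        ref = [_det(100, 100, 200), _det(600, 100, 180)]
        test = [_det(101, 100, 198)]
        rec = evaluate_detections(ref, test, 1.25, (288, 928))
        assert rec.pct_detection == pytest.approx(0.5)
        assert rec.droplets_abs_err_um == pytest.approx((2 + 180) / 2)
        assert rec.detections_abs_err_um == pytest.approx(2.0)
        assert rec.detections_rel_err == pytest.approx(0.01)

    def test_pct_is_count_ratio(self):
        ref = [_det(100 + 200 * i, 100, 180) for i in range(4)]
        rec = evaluate_detections(ref, ref[:3], 1.25, (288, 928))
        assert rec.pct_detection == pytest.approx(0.75)

    def test_empty_reference_flagged(self):
        with pytest.raises(ValueError):
            evaluate_detections([], [_det(1, 1, 200)], 1.25, (64, 64))

    def test_aggregate_ignores_nan_matched_errors(self):
        ref = [_det(100, 100, 200)]
        r1 = evaluate_detections(ref, [], 1.25, (288, 928))       # no match -> NaN
        r2 = evaluate_detections(ref, list(ref), 1.25, (288, 928))
        agg = aggregate_records([r1, r2])
        assert agg["detections_abs_err_um"][0] == pytest.approx(0.0)
        assert agg["pct_detection"][0] == pytest.approx(0.5)
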