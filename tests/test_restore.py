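import numpy as np
import pytest

from dropsizer.degrade import make_pair, upsample_bicubic
from dropsizer.metrics import psnr
from dropsizer.restore_denoise import (DenoiseConfig, build_dncnn, denoise,
                                       load_dncnn, save_dncnn, train_dncnn)
from dropsizer.restore_sr import (SRModelConfig, TrainConfig, _sample_patch,
                                  build_sr_model, load_model, save_model,
                                  super_resolve, train_sr)
from dropsizer.synthgen import DropletImage, SceneSpec, generate_image

TINY_SR = dict(n_blocks=1, feature_channels=8)


@pytest.fixture(scope="module")
def scene_image():
    img, _ = generate_image(
        SceneSpec(droplets=((300, 144, 250.0), (640, 140, 200.0)), seed=9))
    return img


class TestArchitectures:
    def test_srcnn_parameter_count(self):
        model = build_sr_model(SRModelConfig("srcnn", 2))
        # (64x1x9x9 + 64) + (32x64x5x5 + 32) + (1x32x5x5 + 1)
        assert model.n_params() == 5248 + 51232 + 801 == 57281

    def test_srcnn_same_padding_shape(self):
        model = build_sr_model(SRModelConfig("srcnn", 2))
        from dropsizer import nn
        out = model.forward(nn.constant(np.zeros((1, 1, 24, 40), np.float32)))
        assert out.data.shape == (1, 1, 24, 40)

    @pytest.mark.parametrize("scale", [2, 4, 6, 8])
    def test_msrn_scale_contract(self, scale):
        model = build_sr_model(SRModelConfig("msrn_bam", scale, **TINY_SR))
        lr = DropletImage(np.random.default_rng(0).uniform(0, 255, (16, 24))
                          .astype(np.float32), 5.0)
        sr = super_resolve(model, lr)
        assert sr.shape == (16 * scale, 24 * scale)
        assert sr.pixels.min() >= 0 and sr.pixels.max() <= 255
        assert np.isfinite(sr.pixels).all()

    def test_untrained_msrn_equals_bicubic_operator(self, scene_image):
        """The tail is initialised as a Catmull-Rom interpolator, so the
        untrained network reproduces the bicubic baseline."""
        pair = make_pair(scene_image, 2)
        model = build_sr_model(SRModelConfig("msrn_bam", 2, **TINY_SR))
        sr = super_resolve(model, pair.lr)
        bic = upsample_bicubic(pair.lr, 2)
        assert psnr(bic, sr) > 40.0

    def test_super_resolve_deterministic(self):
        model = build_sr_model(SRModelConfig("msrn_bam", 2, **TINY_SR))
        lr = DropletImage(np.random.default_rng(1).uniform(0, 255, (16, 16))
                          .astype(np.float32), 2.5)
        a = super_resolve(model, lr)
        b = super_resolve(model, lr)
        assert np.array_equal(a.pixels, b.pixels)

    def test_unsupported_scale_rejected(self):
        with pytest.raises(ValueError):
            SRModelConfig("msrn_bam", 5)

    def test_dncnn_layer_count_and_shape(self):
        model = build_dncnn(DenoiseConfig(sigma=4.0))
        assert model.n_conv_layers == 19
        from dropsizer import nn
        small = build_dncnn(DenoiseConfig(sigma=4.0, middle_layers=2,
                                          feature_channels=8))
        out = small.forward(nn.constant(np.zeros((1, 1, 20, 30), np.float32)))
        assert out.data.shape == (1, 1, 20, 30)

    def test_zero_weight_dncnn_is_identity(self):
        model = build_dncnn(DenoiseConfig(sigma=4.0, middle_layers=2,
                                          feature_channels=8))
        for p in model.params:
            p.data[:] = 0.0
        img = DropletImage(np.random.default_rng(2).uniform(0, 255, (30, 40))
                           .astype(np.float32), 5.0)
        out = denoise(model, img)
        assert np.abs(out.pixels - img.pixels).max() < 1e-4


class TestTraining:
    def _pairs(self, scene_image, n=2, scale=2):
        return [make_pair(scene_image, scale) for _ in range(n)]

    def test_history_length_and_loss_finite(self, scene_image):
        pairs = self._pairs(scene_image)
        model = build_sr_model(SRModelConfig("msrn_bam", 2, **TINY_SR))
        tc = TrainConfig(epochs=3, steps_per_epoch=2, batch_size=2,
                         patch_size_lr=16, learning_rate=1e-3, seed=0)
        _, hist = train_sr(model, pairs, pairs[:1], tc)
        assert len(hist.train_loss) == 3
        assert len(hist.val_psnr) == 3
        assert 0 <= hist.best_epoch < 3
        assert np.isfinite(hist.train_loss).all()

    def test_training_deterministic_given_seed(self, scene_image):
        pairs = self._pairs(scene_image)
        tc = TrainConfig(epochs=2, steps_per_epoch=2, batch_size=2,
                         patch_size_lr=16, learning_rate=1e-3, seed=5)
        losses = []
        for _ in range(2):
            model = build_sr_model(SRModelConfig("msrn_bam", 2, **TINY_SR, seed=1))
            _, hist = train_sr(model, pairs, [], tc)
            losses.append(hist.train_loss)
        assert np.allclose(losses[0], losses[1], rtol=1e-6)

    def test_scale_mismatch_rejected(self, scene_image):
        pairs = self._pairs(scene_image, scale=4)
        model = build_sr_model(SRModelConfig("msrn_bam", 2, **TINY_SR))
        with pytest.raises(ValueError):
            train_sr(model, pairs, [], TrainConfig(epochs=1))

    def test_augmented_patches_stay_aligned(self, scene_image):
        """LR/HR patches must stay pixel-aligned under flips and rotations."""
        pair = make_pair(scene_image, 2)
        rng = np.random.default_rng(0)
        tc = TrainConfig(epochs=1)
        checked = 0
        for _ in range(60):
            lr, hr = _sample_patch(pair, 32, rng, tc)
            if hr.std() < 5:
                continue  # flat background patch: only sensor noise to correlate
            up = upsample_bicubic(DropletImage(lr, pair.lr.um_per_px), 2)
            corr = np.corrcoef(up.pixels.ravel(), hr.ravel())[0, 1]
            assert corr > 0.9
            checked += 1
        assert checked >= 5

    def test_dncnn_history_and_patch_guard(self, scene_image):
        cfg = DenoiseConfig(sigma=4.0, middle_layers=1, feature_channels=4,
                            epochs=2, steps_per_epoch=2, batch_size=2,
                            patch_size=16, seed=0)
        _, hist = train_dncnn([scene_image], cfg)
        assert len(hist.train_loss) == 2
        with pytest.raises(ValueError):
            train_dncnn([DropletImage(np.zeros((8, 8), np.float32), 1.25)],
                        DenoiseConfig(sigma=4.0, patch_size=40))


class TestCheckpoints:
    def test_sr_roundtrip(self, tmp_path, scene_image):
        model = build_sr_model(SRModelConfig("msrn_bam", 2, **TINY_SR, seed=3))
        path = tmp_path / "m.npz"
        save_model(model, path)
        clone = load_model(path)
        lr = make_pair(scene_image, 2).lr
        assert np.array_equal(super_resolve(model, lr).pixels,
                              super_resolve(clone, lr).pixels)

    def test_dncnn_roundtrip_includes_bn_state(self, tmp_path, scene_image):
        cfg = DenoiseConfig(sigma=4.0, middle_layers=1, feature_channels=4,
                            epochs=1, steps_per_epoch=3, batch_size=2,
                            patch_size=16, seed=0)
        model, _ = train_dncnn([scene_image], cfg)
        path = tmp_path / "d.npz"
        save_dncnn(model, path)
        clone = load_dncnn(path)
        noisy = DropletImage(np.random.default_rng(0).uniform(0, 255, (32, 32))
                             .astype(np.float32), 5.0)
        assert np.array_equal(denoise(model, noisy).pixels,
                              denoise(clone, noisy).pixels)

    def test_kind_mismatch_rejected(self, tmp_path):
        model = build_sr_model(SRModelConfig("msrn_bam", 2, **TINY_SR))
        save_model(model, tmp_path / "m.npz")
        with pytest.raises(ValueError):
            load_dncnn(tmp_path / "m.npz")
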