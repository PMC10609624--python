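"""Residual Gaussian denoising with DnCNN.

The network predicts the *noise* in its input (residual learning): the clean
estimate is ``noisy - R(noisy)``.  One model is trained per noise level; the
architecture is a 3x3 Conv+ReLU head, a body of Conv+BatchNorm+ReLU layers
(17 at full scale) and a final 3x3 Conv reconstructing the residual.  The
final convolution is zero-initialised, so an untrained model is exactly the
identity (residual 0) -- the natural starting point for residual learning.

Training pairs are synthesized on the fly: clean patches are drawn from the
training images and corrupted with fresh Gaussian noise each batch, giving
unlimited pairs at desk scale; a frozen-noise mode fixes one corruption per
image for exact reproducibility of a finite dataset.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from functools import partial

from . import nn
from .metrics import psnr
from .restore_sr import TrainHistory, _snapshot, _restore
from .synthgen import DropletImage

#: all convolutions replicate border pixels so constants pass through
_econv = partial(nn.Conv2d, pad_mode="edge")

__all__ = [
    "DenoiseConfig",
    "DnCNN",
    "build_dncnn",
    "train_dncnn",
    "denoise",
    "save_dncnn",
    "load_dncnn",
]


@dataclass(frozen=True)
class DenoiseConfig:
    """DnCNN architecture + training recipe for one noise level ``sigma``
    (grey levels on the 0-255 scale)."""

    sigma: float
    middle_layers: int = 17
    feature_channels: int = 64
    patch_size: int = 40
    batch_size: int = 32
    learning_rate: float = 1e-4
    epochs: int = 1200
    seed: int = 0
    steps_per_epoch: int | None = None
    frozen_noise: bool = False

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.middle_layers < 1:
            raise ValueError("middle_layers must be >= 1")


class DnCNN:
    """Residual denoiser: Conv+ReLU, N x (Conv+BN+ReLU), Conv."""

    def __init__(self, config: DenoiseConfig):
        self.config = config
        f = config.feature_channels
        rng = np.random.default_rng(config.seed)
        self.head = _econv(1, f, 3, rng)
        self.body: list[tuple[nn.Conv2d, nn.BatchNorm2d]] = []
        for _ in range(config.middle_layers):
            conv = _econv(f, f, 3, rng, bias=False)  # BN absorbs the bias
            self.body.append((conv, nn.BatchNorm2d(f)))
        self.tail = _econv(f, 1, 3, rng, init="zero")
        self._training = True

    @property
    def n_conv_layers(self) -> int:
        return len(self.body) + 2

    @property
    def params(self) -> list[nn.Var]:
        out = list(self.head.params)
        for conv, bn in self.body:
            out += conv.params + bn.params
        out += self.tail.params
        return out

    def set_training(self, training: bool) -> None:
        self._training = training
        for _, bn in self.body:
            bn.training = training

    def forward(self, x: nn.Var) -> nn.Var:
        """Predicted residual (noise estimate), same shape as the input."""
        h = nn.relu(self.head(x))
        for conv, bn in self.body:
            h = nn.relu(bn(conv(h)))
        return self.tail(h)


def build_dncnn(config: DenoiseConfig) -> DnCNN:
    return DnCNN(config)


def recalibrate_bn(model: DnCNN, images: list[DropletImage], sigma: float,
                   seed: int, max_images: int = 8) -> None:
    """Refresh batch-norm running statistics with full-image forward passes.

    Running statistics accumulated with a small momentum lag behind rapidly
    moving weights during short training runs, which degrades inference-mode
    output.  This replaces them with an equal-weight average of the batch
    statistics over noisy full images, the population the model sees at
    inference time.
    """
    rng = np.random.default_rng(seed)
    model.set_training(True)
    saved = [bn.momentum for _, bn in model.body]
    try:
        for k, img in enumerate(images[:max_images]):
            for _, bn in model.body:
                bn.momentum = 1.0 / (k + 1)   # running average of batch stats
            noisy = img.pixels / 255.0 + rng.normal(
                0, sigma / 255.0, img.shape)
            model.forward(nn.constant(noisy[None, None].astype(np.float32)))
    finally:
        for (_, bn), m in zip(model.body, saved):
            bn.momentum = m
        model.set_training(False)


def denoise(model: DnCNN, noisy: DropletImage) -> DropletImage:
    """Clean estimate = noisy - predicted residual, clipped to [0, 255]."""
    model.set_training(False)
    x = noisy.pixels[None, None] / 255.0
    residual = model.forward(nn.constant(x)).data[0, 0]
    out = np.clip((x[0, 0] - residual) * 255.0, 0.0, 255.0).astype(np.float32)
    return DropletImage(out, noisy.um_per_px)


def _denoised_val_psnr(model: DnCNN, val_images: list[DropletImage],
                       sigma: float, seed: int) -> float:
    """Mean PSNR of denoised output on deterministically corrupted images."""
    rng = np.random.default_rng(seed)
    vals = []
    for img in val_images:
        noisy_px = np.clip(
            img.pixels + rng.normal(0, sigma, img.shape), 0, 255
        ).astype(np.float32)
        out = denoise(model, DropletImage(noisy_px, img.um_per_px))
        vals.append(psnr(img, out))
    finite = [v for v in vals if math.isfinite(v)]
    return float(np.mean(finite)) if finite else math.inf


def train_dncnn(train_images: list[DropletImage], config: DenoiseConfig,
                val_images: list[DropletImage] | None = None
                ) -> tuple[DnCNN, TrainHistory]:
    """Train one DnCNN at ``config.sigma``.

    Each batch draws ``patch_size`` square clean patches, corrupts them with
    zero-mean Gaussian noise of std sigma and optimises the L1 distance
    between the predicted residual and the injected noise (Adam).  The model
    returned is the best-validation-PSNR checkpoint.  Deterministic given
    ``config.seed`` up to float rounding.
    """
    if not train_images:
        raise ValueError("training image set is empty")
    p = config.patch_size
    for img in train_images:
        if min(img.shape) < p:
            raise ValueError(f"patch {p} larger than image {img.shape}")
    rng = np.random.default_rng(config.seed)
    model = build_dncnn(config)
    opt = nn.Adam(model.params, lr=config.learning_rate)
    steps = config.steps_per_epoch or max(
        1, math.ceil(len(train_images) / config.batch_size))
    sigma01 = config.sigma / 255.0

    # frozen mode: one corruption per image up front (a fixed finite dataset)
    frozen_noise_maps: list[np.ndarray] | None = None
    if config.frozen_noise:
        frozen_noise_maps = [
            rng.normal(0, sigma01, img.shape).astype(np.float32)
            for img in train_images
        ]
    hist = TrainHistory()
    best = (-math.inf, -1)
    best_snap = _snapshot(model)

    for epoch in range(config.epochs):
        model.set_training(True)
        losses = []
        for _ in range(steps):
            idx = rng.integers(0, len(train_images), size=config.batch_size)
            clean, noise_patches = [], []
            for i in idx:
                px = train_images[i].pixels
                y = int(rng.integers(0, px.shape[0] - p + 1))
                x = int(rng.integers(0, px.shape[1] - p + 1))
                clean.append(px[y:y + p, x:x + p])
                if frozen_noise_maps is not None:
                    noise_patches.append(frozen_noise_maps[i][y:y + p, x:x + p])
            clean_arr = np.stack(clean)[:, None] / 255.0
            if frozen_noise_maps is not None:
                noise = np.stack(noise_patches)[:, None]
            else:
                noise = rng.normal(0, sigma01, clean_arr.shape).astype(np.float32)
            noisy = clean_arr + noise
            pred = model.forward(nn.constant(noisy))
            loss = nn.l1_loss(pred, noise)
            opt.zero_grad()
            nn.backward(loss)
            opt.step()
            losses.append(float(loss.data))
        hist.train_loss.append(float(np.mean(losses)))

        if val_images:
            vp = _denoised_val_psnr(model, val_images, config.sigma,
                                    seed=config.seed + 7919)
            hist.val_psnr.append(vp)
            hist.val_ssim.append(math.nan)
            if vp > best[0]:
                best = (vp, epoch)
                best_snap = _snapshot(model)
        else:
            hist.val_psnr.append(math.nan)
            hist.val_ssim.append(math.nan)

    if val_images:
        hist.best_epoch = best[1]
        _restore(model, best_snap)
    else:
        hist.best_epoch = len(hist.train_loss) - 1
    recalibrate_bn(model, train_images, config.sigma, seed=config.seed + 104729)
    return model, hist


def save_dncnn(model: DnCNN, path: str | Path) -> None:
    cfg = asdict(model.config)
    cfg["__kind__"] = "dncnn"
    arrays = {f"p{i}": p.data for i, p in enumerate(model.params)}
    for i, (_, bn) in enumerate(model.body):
        arrays[f"bn{i}_mean"] = bn.running["mean"]
        arrays[f"bn{i}_var"] = bn.running["var"]
    np.savez(path, __config__=json.dumps(cfg), **arrays)


def load_dncnn(path: str | Path) -> DnCNN:
    with np.load(path, allow_pickle=False) as data:
        cfg = json.loads(str(data["__config__"]))
        kind = cfg.pop("__kind__", None)
        if kind != "dncnn":
            raise ValueError(f"checkpoint at {path} is not a DnCNN model")
        model = DnCNN(DenoiseConfig(**cfg))
        for i, p in enumerate(model.params):
            p.data = data[f"p{i}"].astype(np.float32)
        for i, (_, bn) in enumerate(model.body):
            bn.running["mean"] = data[f"bn{i}_mean"].astype(np.float32)
            bn.running["var"] = data[f"bn{i}_var"].astype(np.float32)
    return model
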