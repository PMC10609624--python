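"""Single-image super-resolution: bicubic baseline, SRCNN and MSRN-BAM.

Two trainable architectures are provided on top of the bicubic baseline:

* **SRCNN** -- the classical three-layer network (9-5-5 filters, 64/32
  features) operating on the bicubic-upsampled LR image.  Unlike the original
  (which crops borders), convolutions are 'same'-padded so output and
  reference dimensions match.
* **MSRN-BAM** -- a multiscale residual network: a head convolution, a chain
  of multiscale residual blocks (parallel 3x3/5x5 branches with
  cross-concatenation and a balanced attention gate), hierarchical feature
  fusion over the head and every block output, and sub-pixel (pixel-shuffle)
  upsampling factorized into prime stages.  The attention gate averages a
  channel branch (global-average-pooled gating) and a spatial branch (a
  single-conv gate).

Networks operate on [0, 1]-normalized intensities internally.  Residual
branches are zero-initialised and the upsampling tail is initialised as a
Catmull-Rom (bicubic) interpolator, so an untrained MSRN-BAM reproduces the
bicubic baseline and optimisation starts at the baseline's operating point
rather than from scratch.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from functools import partial

from . import nn
from .degrade import PairedSample, upsample_bicubic
from .metrics import psnr, ssim
from .synthgen import DropletImage

#: all convolutions replicate border pixels so constants pass through
_econv = partial(nn.Conv2d, pad_mode="edge")

__all__ = [
    "SRModelConfig",
    "TrainConfig",
    "TrainHistory",
    "SRCNN",
    "MSRNBAM",
    "build_sr_model",
    "train_sr",
    "super_resolve",
    "save_model",
    "load_model",
    "scale_factorization",
]

SUPPORTED_SCALES = (2, 4, 6, 8)


def scale_factorization(scale: int) -> list[int]:
    """Prime-stage factorization of the upsampling factor (6 = 2 x 3)."""
    table = {2: [2], 4: [2, 2], 6: [2, 3], 8: [2, 2, 2]}
    if scale not in table:
        raise ValueError(f"unsupported scale {scale}; supported: {SUPPORTED_SCALES}")
    return table[scale]


@dataclass(frozen=True)
class SRModelConfig:
    """Architecture selection.  ``n_blocks``/``feature_channels`` describe the
    MSRN-BAM trunk (8 blocks / 64 channels at full scale; tests use a reduced
    preset)."""

    arch: str
    scale: int
    n_blocks: int = 8
    feature_channels: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arch not in ("srcnn", "msrn_bam"):
            raise ValueError(f"unknown arch {self.arch!r}")
        scale_factorization(self.scale)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation recipe.  Defaults follow the MSRN-BAM recipe (400 epochs,
    batch 16, LR patch 32, Adam 1e-4, L1); :meth:`srcnn_default` switches to
    the SRCNN recipe (300 epochs, batch 32, MSE).  ``steps_per_epoch`` defaults
    to ceil(n_train / batch_size)."""

    epochs: int = 400
    batch_size: int = 16
    patch_size_lr: int = 32
    learning_rate: float = 1e-4
    loss: str = "L1"
    random_crop: bool = True
    hflip: bool = True
    vflip: bool = True
    rot90: bool = True
    seed: int = 0
    steps_per_epoch: int | None = None
    early_stop_window: int | None = None
    early_stop_min_delta: float = 0.03

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.patch_size_lr < 1:
            raise ValueError("epochs, batch_size and patch_size_lr must be positive")
        if self.loss not in ("L1", "MSE"):
            raise ValueError("loss must be 'L1' or 'MSE'")

    @staticmethod
    def srcnn_default(**kw) -> "TrainConfig":
        kw.setdefault("epochs", 300)
        kw.setdefault("batch_size", 32)
        kw.setdefault("loss", "MSE")
        return TrainConfig(**kw)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_psnr: list[float] = field(default_factory=list)
    val_ssim: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _delta_kernel(k: int) -> np.ndarray:
    d = np.zeros((k, k), dtype=np.float32)
    d[k // 2, k // 2] = 1.0
    return d


def _cubic_taps(offset: float, a: float = -0.5) -> np.ndarray:
    """5-tap Catmull-Rom interpolation weights for a sample at ``offset``
    (in input-pixel units, |offset| <= 0.5) from the window centre."""

    def k(t: float) -> float:
        t = abs(t)
        if t <= 1.0:
            return (a + 2) * t**3 - (a + 3) * t**2 + 1
        if t < 2.0:
            return a * (t**3 - 5 * t**2 + 8 * t - 4)
        return 0.0

    return np.array([k(n - offset) for n in range(-2, 3)], dtype=np.float32)


class SRCNN:
    """Three-layer SRCNN; input is the bicubic-upsampled LR image."""

    arch = "srcnn"

    def __init__(self, config: SRModelConfig):
        self.config = config
        self.scale = config.scale
        rng = np.random.default_rng(config.seed)
        self.c1 = _econv(1, 64, 9, rng)
        self.c2 = _econv(64, 32, 5, rng)
        self.c3 = _econv(32, 1, 5, rng)
        # start close to the identity on the interpolated input
        self.c1.w.data[0] = 0.0
        self.c1.w.data[0, 0] = _delta_kernel(9)
        self.c2.w.data[0] = 0.0
        self.c2.w.data[0, 0] = _delta_kernel(5)
        self.c3.w.data[:] = 0.0
        self.c3.w.data[0, 0] = _delta_kernel(5)

    @property
    def params(self) -> list[nn.Var]:
        return self.c1.params + self.c2.params + self.c3.params

    def n_params(self) -> int:
        return sum(p.data.size for p in self.params)

    def forward(self, x: nn.Var) -> nn.Var:
        return self.c3(nn.relu(self.c2(nn.relu(self.c1(x)))))

    def set_training(self, training: bool) -> None:  # no train-time state
        pass


class _MSDRBBAM:
    """One multiscale residual block with balanced attention."""

    def __init__(self, f: int, rng: np.random.Generator):
        self.c3a = _econv(f, f, 3, rng)
        self.c5a = _econv(f, f, 5, rng)
        self.c3b = _econv(2 * f, 2 * f, 3, rng)
        self.c5b = _econv(2 * f, 2 * f, 5, rng)
        self.bottleneck = _econv(4 * f, f, 1, rng, init="zero")
        self.acam = _econv(f, f, 1, rng)   # channel gate on pooled features
        self.msam = _econv(f, 1, 3, rng)   # spatial gate
        self.half = nn.constant(np.float32(0.5))

    @property
    def params(self) -> list[nn.Var]:
        out: list[nn.Var] = []
        for layer in (self.c3a, self.c5a, self.c3b, self.c5b,
                      self.bottleneck, self.acam, self.msam):
            out += layer.params
        return out

    def __call__(self, x: nn.Var) -> nn.Var:
        s1 = nn.concat([nn.relu(self.c3a(x)), nn.relu(self.c5a(x))])
        s2 = nn.concat([nn.relu(self.c3b(s1)), nn.relu(self.c5b(s1))])
        g = self.bottleneck(s2)
        ca = nn.sigmoid(self.acam(nn.global_avg_pool(g)))
        sa = nn.sigmoid(self.msam(g))
        att = nn.mul(nn.add(ca, sa), self.half)
        return nn.add(nn.mul(g, att), x)


class MSRNBAM:
    """Multiscale residual SR network with balanced attention and HFFS."""

    arch = "msrn_bam"

    def __init__(self, config: SRModelConfig):
        self.config = config
        self.scale = config.scale
        f = config.feature_channels
        rng = np.random.default_rng(config.seed)
        self.head = _econv(1, f, 3, rng)
        self.head.w.data[0] = 0.0
        self.head.w.data[0, 0] = _delta_kernel(3)  # channel 0 carries the image
        self.blocks = [_MSDRBBAM(f, rng) for _ in range(config.n_blocks)]
        self.fusion = _econv((config.n_blocks + 1) * f, f, 1, rng, init="zero")
        for c in range(f):  # pass head features straight through at init
            self.fusion.w.data[c, c, 0, 0] = 1.0
        self.stages: list[tuple[nn.Conv2d, int]] = []
        for r in scale_factorization(config.scale):
            conv = _econv(f, f * r * r, 5, rng, init="zero")
            for c in range(f):  # initialise each stage as a bicubic upsampler
                for i in range(r):
                    wy = _cubic_taps((i + 0.5) / r - 0.5)
                    for j in range(r):
                        wx = _cubic_taps((j + 0.5) / r - 0.5)
                        conv.w.data[c * r * r + i * r + j, c] = np.outer(wy, wx)
            self.stages.append((conv, r))
        self.tail = _econv(f, 1, 3, rng, init="zero")
        self.tail.w.data[0, 0] = _delta_kernel(3)

    @property
    def params(self) -> list[nn.Var]:
        out = list(self.head.params)
        for b in self.blocks:
            out += b.params
        out += self.fusion.params
        for conv, _ in self.stages:
            out += conv.params
        out += self.tail.params
        return out

    def n_params(self) -> int:
        return sum(p.data.size for p in self.params)

    def forward(self, x: nn.Var) -> nn.Var:
        h = self.head(x)
        feats = [h]
        cur = h
        for block in self.blocks:
            cur = block(cur)
            feats.append(cur)
        fused = self.fusion(nn.concat(feats))
        for conv, r in self.stages:
            fused = nn.pixel_shuffle(conv(fused), r)
        return self.tail(fused)

    def set_training(self, training: bool) -> None:
        pass


def build_sr_model(config: SRModelConfig):
    """Construct an untrained SR model from its config."""
    if config.arch == "srcnn":
        return SRCNN(config)
    return MSRNBAM(config)


def super_resolve(model, lr_image: DropletImage) -> DropletImage:
    """Apply a model to an LR image; output dims = scale x input dims,
    clipped to [0, 255].  Deterministic: repeated calls are identical."""
    model.set_training(False)
    if model.arch == "srcnn":
        inp = upsample_bicubic(lr_image, model.scale)
        x = inp.pixels[None, None] / 255.0
    else:
        x = lr_image.pixels[None, None] / 255.0
    out = model.forward(nn.constant(x)).data[0, 0]
    out = np.clip(out * 255.0, 0.0, 255.0).astype(np.float32)
    return DropletImage(out, lr_image.um_per_px / model.scale)


def _sample_patch(pair: PairedSample, p: int, rng: np.random.Generator,
                  tc: TrainConfig) -> tuple[np.ndarray, np.ndarray]:
    s = pair.scale
    lh, lw = pair.lr.shape
    if lh < p or lw < p:
        raise ValueError(f"LR image {lh}x{lw} smaller than patch {p}")
    if tc.random_crop:
        y = int(rng.integers(0, lh - p + 1))
        x = int(rng.integers(0, lw - p + 1))
    else:
        y = (lh - p) // 2
        x = (lw - p) // 2
    lr = pair.lr.pixels[y:y + p, x:x + p]
    hr = pair.hr.pixels[y * s:(y + p) * s, x * s:(x + p) * s]
    if tc.hflip and rng.random() < 0.5:
        lr, hr = lr[:, ::-1], hr[:, ::-1]
    if tc.vflip and rng.random() < 0.5:
        lr, hr = lr[::-1], hr[::-1]
    if tc.rot90 and rng.random() < 0.5:
        lr, hr = np.rot90(lr), np.rot90(hr)
    return np.ascontiguousarray(lr), np.ascontiguousarray(hr)


def _snapshot(model) -> list[np.ndarray]:
    return [p.data.copy() for p in model.params]


def _restore(model, snap: list[np.ndarray]) -> None:
    for p, s in zip(model.params, snap):
        p.data = s.copy()


def validation_psnr(model, pairs: list[PairedSample]) -> tuple[float, float]:
    """Mean PSNR/SSIM of the model's output over full validation images."""
    ps, ss = [], []
    for pair in pairs:
        sr = super_resolve(model, pair.lr)
        ps.append(psnr(pair.hr, sr))
        ss.append(ssim(pair.hr, sr))
    finite = [p for p in ps if math.isfinite(p)]
    mean_psnr = float(np.mean(finite)) if finite else math.inf
    return mean_psnr, float(np.mean(ss))


def train_sr(model, train_pairs: list[PairedSample],
             val_pairs: list[PairedSample],
             tc: TrainConfig) -> tuple[object, TrainHistory]:
    """Patch-based training; returns the model restored to its best-validation
    checkpoint together with the per-epoch history.

    SRCNN trains on bicubic-upsampled LR patches against HR patches with MSE;
    MSRN-BAM trains on raw LR patches against aligned HR patches with L1.
    Augmentations (flips, 90-degree rotation) are applied identically to both
    patches of a pair.  Deterministic given ``tc.seed`` up to float rounding.
    """
    for pair in train_pairs + val_pairs:
        if pair.scale != model.scale:
            raise ValueError(
                f"pair scale {pair.scale} != model scale {model.scale}"
            )
    rng = np.random.default_rng(tc.seed)
    opt = nn.Adam(model.params, lr=tc.learning_rate)
    steps = tc.steps_per_epoch or max(1, math.ceil(len(train_pairs) / tc.batch_size))
    loss_fn = nn.l1_loss if tc.loss == "L1" else nn.mse_loss
    s = model.scale
    hist = TrainHistory()
    best = (-math.inf, -1)
    best_snap = _snapshot(model)

    for epoch in range(tc.epochs):
        model.set_training(True)
        losses = []
        for _ in range(steps):
            idx = rng.integers(0, len(train_pairs), size=tc.batch_size)
            lr_batch, hr_batch = [], []
            for i in idx:
                lr, hr = _sample_patch(train_pairs[i], tc.patch_size_lr, rng, tc)
                lr_batch.append(lr)
                hr_batch.append(hr)
            lr_arr = np.stack(lr_batch)[:, None] / 255.0
            hr_arr = np.stack(hr_batch)[:, None] / 255.0
            if model.arch == "srcnn":
                from .degrade import _resize
                up = np.stack([
                    _resize(im[0] * 255.0, (im.shape[1] * s, im.shape[2] * s))
                    for im in lr_arr
                ])[:, None] / 255.0
                pred = model.forward(nn.constant(up))
            else:
                pred = model.forward(nn.constant(lr_arr))
            loss = loss_fn(pred, hr_arr)
            opt.zero_grad()
            nn.backward(loss)
            opt.step()
            losses.append(float(loss.data))
        hist.train_loss.append(float(np.mean(losses)))

        vp, vs = validation_psnr(model, val_pairs) if val_pairs else (math.nan, math.nan)
        hist.val_psnr.append(vp)
        hist.val_ssim.append(vs)
        if val_pairs and vp > best[0]:
            best = (vp, epoch)
            best_snap = _snapshot(model)

        if (tc.early_stop_window and epoch + 1 >= tc.early_stop_window
                and val_pairs):
            window = hist.val_psnr[-tc.early_stop_window:]
            if max(window) - window[0] <= tc.early_stop_min_delta:
                break

    if val_pairs:
        hist.best_epoch = best[1]
        _restore(model, best_snap)
    else:
        hist.best_epoch = len(hist.train_loss) - 1
    return model, hist


def save_model(model, path: str | Path) -> None:
    """Serialize architecture config + parameters to an .npz checkpoint."""
    cfg = asdict(model.config)
    cfg["__kind__"] = "sr"
    arrays = {f"p{i}": p.data for i, p in enumerate(model.params)}
    np.savez(path, __config__=json.dumps(cfg), **arrays)


def load_model(path: str | Path):
    with np.load(path, allow_pickle=False) as data:
        cfg = json.loads(str(data["__config__"]))
        kind = cfg.pop("__kind__", "sr")
        if kind != "sr":
            raise ValueError(f"checkpoint at {path} is not an SR model")
        model = build_sr_model(SRModelConfig(**cfg))
        for i, p in enumerate(model.params):
            p.data = data[f"p{i}"].astype(np.float32)
    return model
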