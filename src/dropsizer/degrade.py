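"""Degradation model: bicubic down/up-sampling, Gaussian corruption, splits.

The low-resolution observation is modelled as ``I_LR = (I_HR (*) K) v_S + N``:
the high-resolution image blurred by a kernel K, decimated by an integer scale
S and corrupted by additive noise N.  Here K is folded into the bicubic
resampling kernel (Catmull-Rom, a = -0.5, area-weighted support when
downscaling -- Pillow's convolution resampler), and N is i.i.d. zero-mean
Gaussian on the 0-255 grey scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from PIL import Image

from .synthgen import DropletImage

__all__ = [
    "PairedSample",
    "NoiseSpec",
    "downsample_bicubic",
    "upsample_bicubic",
    "add_gaussian_noise",
    "make_pair",
    "split_dataset",
]

SUPPORTED_SCALES = (2, 4, 6, 8)


@dataclass(frozen=True)
class PairedSample:
    """An HR image with its LR counterpart at an integer scale factor."""

    hr: DropletImage
    lr: DropletImage
    scale: int

    def __post_init__(self) -> None:
        eh, ew = (d // self.scale for d in self.hr.shape)
        if self.lr.shape != (eh, ew):
            raise ValueError(
                f"LR dims {self.lr.shape} != floor(HR dims / scale) = {(eh, ew)}"
            )


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian corruption: std in grey levels, clipping policy, seed.

    ``clip_mode='none'`` keeps the unbounded float image (useful for closed-form
    PSNR checks), ``'clip'`` clamps to [0, 255], ``'clip_round'`` additionally
    quantizes to integers as an 8-bit sensor would.
    """

    sigma: float
    clip_mode: str = "clip"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.clip_mode not in ("none", "clip", "clip_round"):
            raise ValueError(f"unknown clip_mode {self.clip_mode!r}")


def _resize(pixels: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    im = Image.fromarray(np.asarray(pixels, dtype=np.float32), mode="F")
    out = im.resize((out_hw[1], out_hw[0]), resample=Image.Resampling.BICUBIC)
    return np.asarray(out, dtype=np.float32)


def downsample_bicubic(image: DropletImage, scale: int) -> DropletImage:
    """Bicubic decimation by an integer factor; output dims = floor(in / scale).

    The physical scale (um/px) grows by the same factor.  Values are clipped
    back to [0, 255] (the cubic kernel can overshoot at edges).
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")
    h, w = image.shape
    oh, ow = h // scale, w // scale
    if oh < 8 or ow < 8:
        raise ValueError(f"output {oh}x{ow} too small (needs both dims >= 8)")
    if scale == 1:
        return image
    out = np.clip(_resize(image.pixels, (oh, ow)), 0.0, 255.0)
    return DropletImage(out, image.um_per_px * scale)


def upsample_bicubic(image: DropletImage, scale: int) -> DropletImage:
    """Bicubic interpolation to ``scale`` times the input dimensions."""
    if scale < 1:
        raise ValueError("scale must be >= 1")
    if scale == 1:
        return image
    h, w = image.shape
    out = np.clip(_resize(image.pixels, (h * scale, w * scale)), 0.0, 255.0)
    return DropletImage(out, image.um_per_px / scale)


def make_pair(hr: DropletImage, scale: int) -> PairedSample:
    """Build the HR/LR training pair at the given scale."""
    return PairedSample(hr=hr, lr=downsample_bicubic(hr, scale), scale=scale)


def add_gaussian_noise(image: DropletImage, noise: NoiseSpec) -> DropletImage:
    """Corrupt with i.i.d. zero-mean Gaussian noise; deterministic given seed."""
    if noise.sigma == 0:
        return image
    rng = np.random.default_rng(noise.seed)
    noisy = image.pixels.astype(np.float64) + rng.normal(
        0.0, noise.sigma, size=image.shape
    )
    if noise.clip_mode == "clip":
        noisy = np.clip(noisy, 0.0, 255.0)
    elif noise.clip_mode == "clip_round":
        noisy = np.clip(np.rint(noisy), 0.0, 255.0)
    return DropletImage(noisy.astype(np.float32), image.um_per_px)


def split_dataset(
    items: Sequence[str],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list[str], list[str], list[str]]:
    """Deterministic random partition into train/val/test.

    Subset sizes are ``floor(n * ratio)`` with the remainder distributed by
    largest fractional part, so 100 items at 80:10:10 give exactly 80/10/10.
    The three subsets are disjoint and exhaustive.
    """
    if not items:
        raise ValueError("cannot split an empty manifest")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    n = len(items)
    exact = [n * r for r in ratios]
    counts = [int(np.floor(e)) for e in exact]
    remainder = n - sum(counts)
    order = sorted(range(3), key=lambda i: exact[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    shuffled = [items[i] for i in perm]
    train = shuffled[: counts[0]]
    val = shuffled[counts[0] : counts[0] + counts[1]]
    test = shuffled[counts[0] + counts[1] :]
    return train, val, test
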