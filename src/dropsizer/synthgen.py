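"""Synthetic flow-focusing microchannel scenes with known droplet ground truth.

Real acquisitions of this kind are bright-field images of a glass flow-focusing
microchannel: a homogeneously backlit background, two dark horizontal channel
walls, and near-spherical droplets advected along the channel.  Because the two
liquid phases are refractive-index matched, a droplet appears only as a thin,
low-contrast dark ring (the interface); its interior matches the background.

This module renders that geometry with exact, analytically known ground truth
(centre, diameter) for every droplet, so detectors and restoration models can
be scored against truth without any experimental data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "SceneSpec",
    "GroundTruthCircle",
    "DropletImage",
    "DEFAULT_UM_PER_PX",
    "generate_image",
    "ground_truth_mask",
    "rasterize_disk",
    "random_scene",
    "generate_dataset",
    "read_manifest",
]

#: Default image scale in micrometres per pixel.  The physical anchors available
#: for this kind of acquisition (droplets of 125 um spanning ~96 px up to 275 um
#: spanning ~230 px) bracket 1.20-1.30 um/px; 1.25 splits the range.
DEFAULT_UM_PER_PX = 1.25

#: Default scene geometry: the camera's zone of interest around the main channel.
DEFAULT_HEIGHT = 288
DEFAULT_WIDTH = 928
DEFAULT_WALLS = (6, 282)
DEFAULT_BACKGROUND = 200.0


@dataclass(frozen=True)
class DropletImage:
    """A 2-D grey-level raster on the 0-255 working scale with a physical scale.

    ``pixels`` is float32; every stage of the pipeline consumes and produces
    this unit.  Values are always within [0, 255].
    """

    pixels: np.ndarray
    um_per_px: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float32)
        if px.ndim != 2:
            raise ValueError(f"expected 2-D grey-level raster, got shape {px.shape}")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class GroundTruthCircle:
    """One true droplet: centre in pixel coordinates, diameter in um and px."""

    center_x_px: float
    center_y_px: float
    diameter_um: float
    diameter_px: float

    @property
    def radius_px(self) -> float:
        return self.diameter_px / 2.0


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic scene.

    Droplets are given as ``(center_x_px, center_y_px, diameter_um)`` tuples.
    ``interface_contrast`` is the depth of the dark interface ring as a fraction
    of the background level; index-matched phases give low values (~0.2-0.4),
    mismatched phases give strong rings (~0.7-0.9).
    """

    image_height_px: int = DEFAULT_HEIGHT
    image_width_px: int = DEFAULT_WIDTH
    um_per_px: float = DEFAULT_UM_PER_PX
    background_level: float = DEFAULT_BACKGROUND
    wall_positions_px: tuple[int, int] = DEFAULT_WALLS
    droplets: tuple[tuple[float, float, float], ...] = ()
    interface_width_px: float = 2.0
    interface_contrast: float = 0.35
    sensor_noise_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if not 0.0 <= self.background_level <= 255.0:
            raise ValueError("background_level must be within [0, 255]")
        if self.interface_width_px < 1.0:
            raise ValueError("interface_width_px must be >= 1")
        if not 0.0 < self.interface_contrast <= 1.0:
            raise ValueError("interface_contrast must be in (0, 1]")
        if self.sensor_noise_sigma < 0:
            raise ValueError("sensor_noise_sigma must be non-negative")
        object.__setattr__(self, "droplets", tuple(tuple(d) for d in self.droplets))
        for cx, cy, d_um in self.droplets:
            if d_um <= 0:
                raise ValueError(f"droplet diameter must be positive, got {d_um}")
            if not (0 <= cx < self.image_width_px and 0 <= cy < self.image_height_px):
                raise ValueError(f"droplet centre ({cx}, {cy}) outside image bounds")

    def circles(self) -> list[GroundTruthCircle]:
        return [
            GroundTruthCircle(cx, cy, d_um, d_um / self.um_per_px)
            for cx, cy, d_um in self.droplets
        ]


def _coordinate_grids(height: int, width: int) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[0:height, 0:width]
    return yy.astype(np.float64), xx.astype(np.float64)


def generate_image(spec: SceneSpec) -> tuple[DropletImage, list[GroundTruthCircle]]:
    """Render a scene to a grey-level image plus its ground-truth circle list.

    Deterministic given ``spec.seed``.  The droplet interface is a
    Gaussian-profiled dark annulus of depth ``interface_contrast x background``
    centred on the true circle; the droplet interior equals the background
    (index-matched phases).  Sensor noise is added after compositing and the
    result clipped to [0, 255].
    """
    h, w = spec.image_height_px, spec.image_width_px
    img = np.full((h, w), spec.background_level, dtype=np.float64)

    # Channel walls: dark bands a few pixels thick with a soft inner edge.
    rows = np.arange(h, dtype=np.float64)
    for wall_row in spec.wall_positions_px:
        dist = np.abs(rows - wall_row)
        profile = 0.55 * spec.background_level * np.exp(-(dist**2) / (2 * 2.0**2))
        img -= profile[:, None]

    yy, xx = _coordinate_grids(h, w)
    sigma = spec.interface_width_px / 2.355  # interface_width_px is the ring FWHM
    depth = spec.interface_contrast * spec.background_level
    for cx, cy, d_um in spec.droplets:
        r = (d_um / spec.um_per_px) / 2.0
        dist = np.hypot(yy - cy, xx - cx)
        img -= depth * np.exp(-((dist - r) ** 2) / (2 * sigma**2))

    if spec.sensor_noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.sensor_noise_sigma, size=img.shape)

    np.clip(img, 0.0, 255.0, out=img)
    return DropletImage(img.astype(np.float32), spec.um_per_px), spec.circles()


def rasterize_disk(
    shape: tuple[int, int], cx: float, cy: float, radius_px: float
) -> np.ndarray:
    """Filled-disk boolean mask: pixel set iff its centre lies strictly inside
    the circle.  This rule is the package-wide rasterization convention; the
    metrics module rasterizes detections with the same rule.
    """
    if radius_px <= 0:
        raise ValueError("radius must be positive")
    yy, xx = _coordinate_grids(*shape)
    return (yy - cy) ** 2 + (xx - cx) ** 2 < radius_px**2


def ground_truth_mask(
    circles: Sequence[GroundTruthCircle], shape: tuple[int, int]
) -> list[np.ndarray]:
    """One filled-disk binary mask per ground-truth circle."""
    if shape[0] <= 0 or shape[1] <= 0:
        raise ValueError("shape must be positive")
    return [
        rasterize_disk(shape, c.center_x_px, c.center_y_px, c.radius_px)
        for c in circles
    ]


@dataclass(frozen=True)
class SceneRanges:
    """Randomisation ranges for :func:`random_scene` / :func:`generate_dataset`."""

    n_droplets: tuple[int, int] = (2, 4)
    diameter_um: tuple[float, float] = (160.0, 330.0)
    center_y_jitter_px: float = 10.0
    min_gap_px: float = 12.0


def random_scene(
    template: SceneSpec, rng: np.random.Generator, ranges: SceneRanges | None = None
) -> SceneSpec:
    """Draw a randomized scene from a template: droplet count, diameters and
    positions sampled from ``ranges``, droplets placed left-to-right without
    overlap (dripping-regime trains are monodisperse and well separated)."""
    ranges = ranges or SceneRanges()
    n = int(rng.integers(ranges.n_droplets[0], ranges.n_droplets[1] + 1))
    h, w = template.image_height_px, template.image_width_px
    mid_y = (template.wall_positions_px[0] + template.wall_positions_px[1]) / 2.0

    droplets: list[tuple[float, float, float]] = []
    cursor = 0.0
    for _ in range(n):
        d_um = float(rng.uniform(*ranges.diameter_um))
        r_px = d_um / template.um_per_px / 2.0
        lo = max(cursor + r_px, r_px * 0.6)
        hi = w - r_px * 0.6
        if lo >= hi:
            break  # channel full
        cx = float(rng.uniform(lo, min(lo + 2.5 * r_px, hi)))
        cy = float(
            np.clip(
                mid_y + rng.uniform(-ranges.center_y_jitter_px, ranges.center_y_jitter_px),
                0,
                h - 1,
            )
        )
        droplets.append((cx, cy, d_um))
        cursor = cx + r_px + ranges.min_gap_px
    return replace(template, droplets=tuple(droplets), seed=int(rng.integers(2**31)))


MANIFEST_COLUMNS = ["image", "droplet_id", "cx_px", "cy_px", "d_um", "d_px"]


def generate_dataset(
    out_dir: str | Path,
    n: int,
    seed: int,
    template: SceneSpec | None = None,
    ranges: SceneRanges | None = None,
) -> Path:
    """Write ``n`` randomized scenes as 8-bit PNGs plus a CSV manifest of every
    ground-truth circle; returns the manifest path.  Generator parameters are
    recorded alongside in YAML."""
    from . import cli_io  # local import: avoid cycle at module load

    if n < 1:
        raise ValueError("n must be >= 1")
    template = template or SceneSpec()
    ranges = ranges or SceneRanges()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for i in range(n):
            spec = random_scene(template, rng, ranges)
            image, circles = generate_image(spec)
            name = f"scene_{i:05d}.png"
            cli_io.write_image(image, out_dir / name)
            for j, c in enumerate(circles):
                writer.writerow(
                    [name, j, f"{c.center_x_px:.3f}", f"{c.center_y_px:.3f}",
                     f"{c.diameter_um:.3f}", f"{c.diameter_px:.3f}"]
                )

    params = {
        "n_images": n,
        "seed": seed,
        "template": {
            "image_height_px": template.image_height_px,
            "image_width_px": template.image_width_px,
            "um_per_px": template.um_per_px,
            "background_level": template.background_level,
            "wall_positions_px": list(template.wall_positions_px),
            "interface_width_px": template.interface_width_px,
            "interface_contrast": template.interface_contrast,
            "sensor_noise_sigma": template.sensor_noise_sigma,
        },
        "ranges": {
            "n_droplets": list(ranges.n_droplets),
            "diameter_um": list(ranges.diameter_um),
        },
    }
    with open(out_dir / "params.yaml", "w") as fh:
        yaml.safe_dump(params, fh)
    return manifest


def read_manifest(path: str | Path) -> dict[str, list[GroundTruthCircle]]:
    """Manifest CSV -> mapping of image filename to its ground-truth circles."""
    out: dict[str, list[GroundTruthCircle]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.setdefault(row["image"], []).append(
                GroundTruthCircle(
                    float(row["cx_px"]), float(row["cy_px"]),
                    float(row["d_um"]), float(row["d_px"]),
                )
            )
    return out
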