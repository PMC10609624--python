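"""Droplet detection and diameter measurement.

Two detectors are provided:

* :func:`detect_cht` -- the classical route: Canny edges followed by a circular
  Hough transform (CHT) over the physically admissible radius range, peak
  extraction and non-maximum suppression.
* :func:`detect_sam_cht` -- the mask-guided route: a segmentation backend
  proposes per-object binary masks, and CHT run on each mask's contour extracts
  the single most likely circle.  With a promptable foundation-model backend
  this is the "segment, then size" detector; the shipped ``gt`` and
  ``intensity`` backends make the same code path testable without external
  weights.

Index-matched droplets have faint interface rings, which starves the Canny
stage of edges on degraded images; mask contours are binary and razor sharp,
which is why the mask-guided route degrades much more gracefully.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import canny, peak_local_max
from skimage.morphology import convex_hull_image, disk
from skimage.transform import hough_circle

from .synthgen import DropletImage, GroundTruthCircle, rasterize_disk

__all__ = [
    "CircleDetection",
    "DetectorParams",
    "CapabilityError",
    "SegmentationBackend",
    "GroundTruthBackend",
    "IntensityBackend",
    "SamBackend",
    "get_backend",
    "detect_cht",
    "segment_auto",
    "mask_to_circles",
    "detect_sam_cht",
]


@dataclass(frozen=True)
class CircleDetection:
    """One detected droplet: centre (px), diameter (px and um), score."""

    center_x_px: float
    center_y_px: float
    diameter_px: float
    diameter_um: float
    score: float

    @property
    def radius_px(self) -> float:
        return self.diameter_px / 2.0


@dataclass(frozen=True)
class DetectorParams:
    """Detector configuration.

    Diameter bounds default to the physically admissible window for this
    channel geometry (130 um up to the 390 um channel depth).  Canny hysteresis
    thresholds are fractions of the per-image gradient-magnitude maximum.
    ``min_score`` is an absolute floor on the normalized Hough accumulator
    (fraction of the circle perimeter supported by edges) in addition to the
    per-image relative ``hough_peak_threshold``.
    """

    canny_sigma: float = 1.0
    min_diameter_um: float = 130.0
    max_diameter_um: float = 390.0
    canny_low_frac: float = 0.10
    canny_high_frac: float = 0.20
    hough_peak_threshold: float = 0.4
    min_score: float = 0.30
    max_circles_per_image: int = 10
    radius_step_px: int = 2
    exclude_border_masks: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.min_diameter_um < self.max_diameter_um:
            raise ValueError("need 0 < min_diameter_um < max_diameter_um")
        for f in (self.canny_low_frac, self.canny_high_frac,
                  self.hough_peak_threshold):
            if not 0.0 < f < 1.0:
                raise ValueError("fractional thresholds must be in (0, 1)")

    def radius_range_px(self, um_per_px: float) -> tuple[int, int]:
        r_min = int(round(self.min_diameter_um / um_per_px / 2.0))
        r_max = int(round(self.max_diameter_um / um_per_px / 2.0))
        if r_min < 2 or r_max <= r_min:
            raise ValueError(
                f"diameter bounds map to an unusable radius range "
                f"[{r_min}, {r_max}] px at {um_per_px} um/px"
            )
        return r_min, r_max


class CapabilityError(RuntimeError):
    """A requested segmentation backend is unknown or unavailable."""


def _canny_edges(image: DropletImage, params: DetectorParams) -> np.ndarray:
    img = image.pixels.astype(np.float64) / 255.0
    smoothed = ndimage.gaussian_filter(img, params.canny_sigma)
    gy = ndimage.sobel(smoothed, axis=0)
    gx = ndimage.sobel(smoothed, axis=1)
    gmax = float(np.hypot(gy, gx).max())
    if gmax == 0.0:
        return np.zeros(image.shape, dtype=bool)
    edges = canny(
        img,
        sigma=params.canny_sigma,
        low_threshold=params.canny_low_frac * gmax,
        high_threshold=params.canny_high_frac * gmax,
        use_quantiles=False,
    )
    # full-width straight edges (channel walls) cannot belong to a droplet
    # and only inflate the voting cost
    edges[edges.mean(axis=1) > 0.5] = False
    return edges


def _parabolic_radius(score: float, s_minus: float, s_plus: float,
                      radius: float, step: float = 1.0) -> float:
    denom = s_minus - 2.0 * score + s_plus
    if denom >= 0.0:
        return radius
    dr = 0.5 * (s_minus - s_plus) / denom
    return radius + float(np.clip(dr, -0.5, 0.5)) * step


def _hough_candidates(
    edges: np.ndarray,
    radii: np.ndarray,
    peaks_per_chunk: int = 16,
    min_xy_distance: int = 8,
) -> list[tuple[float, int, int, float]]:
    """Candidate circles from the normalized Hough accumulator.

    The stack is processed in radius chunks (one-radius overlap, bounded
    memory).  Per chunk, spatial peaks are extracted from the max-projection
    over radii — a centre's best radius is all later stages ever use, so this
    is equivalent to per-radius extraction but ~50x fewer peak searches.
    The winning radius is refined to sub-pixel precision by a 3-point
    parabola across adjacent radii.
    """
    cands: list[tuple[float, int, int, float]] = []
    chunk = 24
    n = len(radii)
    start = 0
    while start < n:
        lo = max(start - 1, 0)
        hi = min(start + chunk + 1, n)
        sub = radii[lo:hi]
        step = float(sub[1] - sub[0]) if len(sub) > 1 else 1.0
        hspace = hough_circle(edges, sub, normalize=True)
        core_lo = start - lo
        core_hi = min(start + chunk, n) - lo
        proj = hspace[core_lo:core_hi].max(axis=0)
        peaks = peak_local_max(
            proj,
            min_distance=min_xy_distance,
            threshold_abs=1e-3,
            num_peaks=peaks_per_chunk,
        )
        for y, x in peaks:
            k = core_lo + int(np.argmax(hspace[core_lo:core_hi, y, x]))
            s = float(hspace[k, y, x])
            sm = float(hspace[k - 1, y, x]) if k > 0 else s
            sp = float(hspace[k + 1, y, x]) if k + 1 < len(sub) else s
            cands.append((s, int(y), int(x),
                          _parabolic_radius(s, sm, sp, sub[k], step)))
        start += chunk
    return cands


def _nms_circles(cands: Sequence[tuple[float, int, int, float]],
                 max_keep: int) -> list[tuple[float, int, int, float]]:
    """Greedy non-maximum suppression: no accepted centre may lie inside a
    previously accepted circle."""
    kept: list[tuple[float, int, int, float]] = []
    for s, y, x, r in sorted(cands, key=lambda c: -c[0]):
        inside = any(
            math.hypot(y - ky, x - kx) < kr for _, ky, kx, kr in kept
        )
        if not inside:
            kept.append((s, y, x, r))
        if len(kept) >= max_keep:
            break
    return kept


def _refine_radius_trough(image: DropletImage, cy: float, cx: float,
                          r: float, half_window: int = 5) -> float:
    """Refine a circle radius to the intensity minimum of the interface ring.

    The droplet interface is a dark annulus whose trough marks the true
    boundary; Canny edges sit on the flanks of that annulus (maximum
    gradient), biasing the Hough radius outward or inward by roughly the ring
    half-width.  The mean intensity over one-pixel annuli around the detected
    centre is parabola-interpolated to a sub-pixel trough radius.
    """
    h, w = image.shape
    lo = max(2, int(round(r)) - half_window)
    hi = int(round(r)) + half_window
    y0, y1 = max(0, int(cy - hi - 1)), min(h, int(cy + hi + 2))
    x0, x1 = max(0, int(cx - hi - 1)), min(w, int(cx + hi + 2))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(yy - cy, xx - cx)
    profile = []
    for rr in range(lo, hi + 1):
        sel = (dist >= rr - 0.5) & (dist < rr + 0.5)
        if not sel.any():
            return r
        profile.append(float(image.pixels[y0:y1, x0:x1][sel].mean()))
    k = int(np.argmin(profile))
    if k == 0 or k == len(profile) - 1:
        return r
    a, b, c = profile[k - 1], profile[k], profile[k + 1]
    denom = a - 2 * b + c
    dr = 0.5 * (a - c) / denom if denom > 0 else 0.0
    refined = lo + k + float(np.clip(dr, -0.5, 0.5))
    return refined if abs(refined - r) <= half_window else r


def detect_cht(image: DropletImage,
               params: DetectorParams | None = None) -> list[CircleDetection]:
    """Classical Canny + circular-Hough droplet detector.

    Peaks must exceed both ``hough_peak_threshold`` of the per-image maximum
    and the absolute ``min_score`` floor; surviving peaks undergo NMS and the
    winning radii are refined to the interface-ring intensity trough.
    Detections are returned sorted by descending score.
    """
    params = params or DetectorParams()
    r_min, r_max = params.radius_range_px(image.um_per_px)
    edges = _canny_edges(image, params)
    if not edges.any():
        return []
    radii = np.arange(r_min, r_max + 1, params.radius_step_px)
    cands = _hough_candidates(edges, radii, min_xy_distance=max(8, r_min // 2))
    if not cands:
        return []
    top = max(c[0] for c in cands)
    thr = max(params.hough_peak_threshold * top, params.min_score)
    cands = [c for c in cands if c[0] >= thr]
    kept = _nms_circles(cands, params.max_circles_per_image)
    out = []
    for s, y, x, r in kept:
        r = _refine_radius_trough(image, y, x, r)
        out.append(
            CircleDetection(
                center_x_px=float(x), center_y_px=float(y),
                diameter_px=2.0 * r, diameter_um=2.0 * r * image.um_per_px,
                score=s,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Segmentation backends
# ---------------------------------------------------------------------------

class SegmentationBackend(Protocol):
    """Backend contract: per-object binary masks with optional confidence."""

    def segment(self, image: DropletImage) -> list[tuple[np.ndarray, float]]:
        """Return (mask, confidence) pairs; masks are boolean, image-shaped."""
        ...


class GroundTruthBackend:
    """Oracle backend: rasterizes known ground-truth circles into masks."""

    def __init__(self, circles: Sequence[GroundTruthCircle]):
        self.circles = list(circles)

    def segment(self, image: DropletImage) -> list[tuple[np.ndarray, float]]:
        return [
            (rasterize_disk(image.shape, c.center_x_px, c.center_y_px, c.radius_px), 1.0)
            for c in self.circles
        ]


class IntensityBackend:
    """Self-contained backend: interface-ring enhancement + thresholding.

    Droplets appear as dark rings on a bright background, so the backend
    thresholds the smoothed darkness map (background minus image), suppresses
    the full-width wall bands, closes small ring gaps and takes the convex hull
    of each remaining ring component -- droplets are convex, so the hull of a
    (possibly broken) ring is the filled droplet.
    """

    def __init__(self, smooth_sigma: float = 1.5, rel_threshold: float = 0.2,
                 abs_threshold: float = 3.0, min_component_px: int = 50,
                 closing_radius: int = 5):
        self.smooth_sigma = smooth_sigma
        self.rel_threshold = rel_threshold
        self.abs_threshold = abs_threshold
        self.min_component_px = min_component_px
        self.closing_radius = closing_radius

    def segment(self, image: DropletImage) -> list[tuple[np.ndarray, float]]:
        px = image.pixels.astype(np.float64)
        bg = float(np.median(px))
        darkness = np.clip(bg - px, 0.0, None)

        # Channel walls darken entire rows (droplets never cover more than
        # ~half the channel length), so wall rows stand out in the row median.
        row_med = np.median(darkness, axis=1)
        wall_rows = row_med > max(3.0, 2.5 * float(np.median(row_med)))
        darkness[wall_rows] = 0.0

        sm = ndimage.gaussian_filter(darkness, self.smooth_sigma)
        thr = max(self.abs_threshold, self.rel_threshold * float(sm.max()))
        binary = ndimage.binary_closing(
            sm > thr, structure=disk(self.closing_radius))

        labels, n = ndimage.label(binary)
        w = image.shape[1]
        out: list[tuple[np.ndarray, float]] = []
        for lab in range(1, n + 1):
            comp = labels == lab
            if comp.sum() < self.min_component_px:
                continue
            cols = np.flatnonzero(comp.any(axis=0))
            if cols.size and (cols[-1] - cols[0]) > 0.9 * w:
                continue  # residual wall band
            # droplets are convex: the hull of a (possibly broken) ring or
            # arc is the filled droplet (or a chord segment of it)
            hull = convex_hull_image(comp)
            conf = float(min(1.0, sm[comp].mean() / max(thr, 1e-9)))
            out.append((hull, conf))
        return out


class SamBackend:
    """Adapter for the Segment Anything foundation model (optional).

    Prompts the automatic mask generator with an evenly spaced point grid.
    Requires the ``segment-anything`` package and a checkpoint on the host;
    otherwise raises :class:`CapabilityError`.  Never silently falls back.
    """

    def __init__(self, checkpoint: str, model_type: str = "vit_b",
                 points_per_side: int = 32, pred_iou_thresh: float = 0.88):
        try:
            from segment_anything import (  # type: ignore
                SamAutomaticMaskGenerator, sam_model_registry)
        except ImportError as exc:
            raise CapabilityError(
                "segment-anything is not installed; the 'sam' backend is "
                "unavailable (use 'gt' or 'intensity')"
            ) from exc
        try:
            sam = sam_model_registry[model_type](checkpoint=checkpoint)
        except (FileNotFoundError, KeyError) as exc:
            raise CapabilityError(
                f"cannot load SAM checkpoint {checkpoint!r}: {exc}"
            ) from exc
        self._generator = SamAutomaticMaskGenerator(
            sam, points_per_side=points_per_side, pred_iou_thresh=pred_iou_thresh
        )

    def segment(self, image: DropletImage) -> list[tuple[np.ndarray, float]]:
        rgb = np.repeat(
            image.pixels.astype(np.uint8)[:, :, None], 3, axis=2
        )
        records = self._generator.generate(rgb)
        return [
            (np.asarray(r["segmentation"], dtype=bool), float(r["predicted_iou"]))
            for r in records
        ]


_BACKENDS = {
    "gt": GroundTruthBackend,
    "intensity": IntensityBackend,
    "sam": SamBackend,
}


def get_backend(name: str, **kwargs) -> SegmentationBackend:
    """Instantiate a registered backend by name; unknown names raise
    :class:`CapabilityError`."""
    try:
        factory = _BACKENDS[name]
    except KeyError:
        raise CapabilityError(
            f"unknown segmentation backend {name!r}; "
            f"registered: {sorted(_BACKENDS)}"
        ) from None
    return factory(**kwargs)


def segment_auto(image: DropletImage,
                 backend: SegmentationBackend | str,
                 params: DetectorParams | None = None,
                 min_confidence: float = 0.0) -> list[np.ndarray]:
    """Run a segmentation backend and filter its masks.

    Masks are kept if their area lies within the disk-area window implied by
    the diameter bounds (with generous margins for imperfect masks) and their
    backend confidence reaches ``min_confidence``.  Masks touching the image
    left/right border are kept by default (forming droplets at the inlet are
    legitimate objects); set ``params.exclude_border_masks`` to drop them.
    """
    params = params or DetectorParams()
    if isinstance(backend, str):
        backend = get_backend(backend)
    r_min, r_max = params.radius_range_px(image.um_per_px)
    area_lo = 0.5 * math.pi * r_min**2
    area_hi = 2.0 * math.pi * r_max**2
    out = []
    for mask, conf in backend.segment(image):
        if mask.shape != image.shape:
            raise ValueError("backend mask shape differs from image shape")
        area = int(mask.sum())
        if not area_lo <= area <= area_hi:
            continue
        if conf < min_confidence:
            continue
        if params.exclude_border_masks:
            if mask[:, 0].any() or mask[:, -1].any():
                continue
        out.append(np.asarray(mask, dtype=bool))
    return out


def _mask_contours(mask: np.ndarray) -> np.ndarray:
    inner = mask & ~ndimage.binary_erosion(mask)
    outer = ndimage.binary_dilation(mask) & ~mask
    return inner | outer


def mask_to_circles(masks: Sequence[np.ndarray],
                    params: DetectorParams,
                    um_per_px: float) -> list[CircleDetection]:
    """Extract the single most likely circle from each mask via CHT.

    The Hough transform runs on the mask's inner+outer contour restricted to
    its padded bounding box; the radius search is narrowed around the mask's
    equivalent-area radius and the winning radius refined by a 3-point
    parabola.  Masks yielding no in-bounds circle are dropped.
    """
    r_min, r_max = params.radius_range_px(um_per_px)
    out: list[CircleDetection] = []
    for mask in masks:
        mask = np.asarray(mask, dtype=bool)
        pts = np.argwhere(mask)
        if pts.size == 0:
            continue
        r_eq = math.sqrt(mask.sum() / math.pi)
        y0, x0 = pts.min(axis=0)
        y1, x1 = pts.max(axis=0)
        # partial-arc masks (e.g. a ring clipped by the channel wall) have a
        # small equivalent radius but a bounding box on the true circle's
        # scale, so the search window honours both
        diag = math.hypot(y1 - y0 + 1, x1 - x0 + 1)
        lo = max(r_min, int(0.5 * r_eq))
        hi = min(r_max, int(max(1.6 * r_eq, 0.8 * diag)) + 1)
        if lo > hi:
            continue
        pad = hi + 2
        ya, yb = max(0, y0 - pad), min(mask.shape[0], y1 + pad + 1)
        xa, xb = max(0, x0 - pad), min(mask.shape[1], x1 + pad + 1)
        edges = _mask_contours(mask[ya:yb, xa:xb])
        radii = np.arange(lo, hi + 1)
        hspace = hough_circle(edges, radii, normalize=True)
        k, y, x = np.unravel_index(int(np.argmax(hspace)), hspace.shape)
        score = float(hspace[k, y, x])
        if score <= 0.0:
            continue
        sm = float(hspace[k - 1, y, x]) if k > 0 else score
        sp = float(hspace[k + 1, y, x]) if k + 1 < len(radii) else score
        r = _parabolic_radius(score, sm, sp, radii[k])
        d_px = 2.0 * r
        d_um = d_px * um_per_px
        if not params.min_diameter_um <= d_um <= params.max_diameter_um:
            continue
        out.append(
            CircleDetection(
                center_x_px=float(x + xa), center_y_px=float(y + ya),
                diameter_px=d_px, diameter_um=d_um, score=score,
            )
        )
    return out


def detect_sam_cht(image: DropletImage,
                   backend: SegmentationBackend | str,
                   params: DetectorParams | None = None) -> list[CircleDetection]:
    """Mask-guided detector: segmentation backend -> per-mask CHT -> dedupe."""
    params = params or DetectorParams()
    masks = segment_auto(image, backend, params)
    dets = mask_to_circles(masks, params, image.um_per_px)
    dets.sort(key=lambda d: -d.score)
    kept: list[CircleDetection] = []
    for d in dets:
        dup = any(
            math.hypot(d.center_x_px - k.center_x_px,
                       d.center_y_px - k.center_y_px)
            < 0.5 * min(d.radius_px, k.radius_px)
            for k in kept
        )
        if not dup:
            kept.append(d)
    return kept
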