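"""Evaluation metrics: Dice, IoU, PSNR, SSIM, detection matching and the
two-tier diameter-error accounting.

Detection quality is always judged against a *reference* detection set (ground
truth, or detections on the high-resolution image).  Percentage detection is
the per-image ratio of test to reference detections; the *droplets* absolute
error averages |d_ref - d_test| over every reference droplet with misses
counted as diameter 0, while the *detections* absolute/relative errors average
over matched pairs only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.metrics import structural_similarity

from .synthgen import DropletImage, rasterize_disk

__all__ = [
    "QualityReport",
    "MatchResult",
    "EvaluationRecord",
    "dice",
    "iou",
    "psnr",
    "ssim",
    "quality_report",
    "match_detections",
    "evaluate_detections",
    "aggregate_records",
]


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); two empty masks count as 1."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    _check_same_shape(a, b)
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index |A∩B| / |A∪B|; two empty masks count as 1."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    _check_same_shape(a, b)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def psnr(ref: DropletImage | np.ndarray, test: DropletImage | np.ndarray,
         peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio 10·log10(L²/MSE) in dB; +inf when identical."""
    r = ref.pixels if isinstance(ref, DropletImage) else np.asarray(ref)
    t = test.pixels if isinstance(test, DropletImage) else np.asarray(test)
    _check_same_shape(r, t)
    mse = float(np.mean((r.astype(np.float64) - t.astype(np.float64)) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(peak**2 / mse)


def ssim(ref: DropletImage | np.ndarray, test: DropletImage | np.ndarray,
         peak: float = 255.0, win_size: int = 11, sigma: float = 1.5,
         k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean structural similarity over Gaussian-weighted sliding windows.

    Windowed convention (11x11, sigma 1.5, K1=0.01, K2=0.03, population
    statistics); luminance/contrast/structure exponents all 1.
    """
    r = ref.pixels if isinstance(ref, DropletImage) else np.asarray(ref)
    t = test.pixels if isinstance(test, DropletImage) else np.asarray(test)
    _check_same_shape(r, t)
    if min(r.shape) < win_size:
        raise ValueError(f"image smaller than the {win_size}x{win_size} window")
    return float(
        structural_similarity(
            r.astype(np.float64), t.astype(np.float64), data_range=peak,
            gaussian_weights=True, sigma=sigma, win_size=win_size,
            use_sample_covariance=False, K1=k1, K2=k2,
        )
    )


@dataclass(frozen=True)
class QualityReport:
    """PSNR/SSIM/MSE of one restored image against its reference."""

    psnr_db: float
    ssim: float
    mse: float
    peak: float = 255.0


def quality_report(ref: DropletImage, test: DropletImage,
                   peak: float = 255.0) -> QualityReport:
    r = ref.pixels.astype(np.float64)
    t = test.pixels.astype(np.float64)
    _check_same_shape(r, t)
    mse = float(np.mean((r - t) ** 2))
    return QualityReport(psnr(ref, test, peak), ssim(ref, test, peak), mse, peak)


@dataclass(frozen=True)
class MatchResult:
    """One-to-one correspondence between reference and test detections."""

    pairs: list[tuple[int, int, float]]
    unmatched_ref: list[int]
    unmatched_test: list[int]


def match_detections(ref: Sequence, test: Sequence,
                     max_dist_frac: float = 0.5) -> MatchResult:
    """Greedy mutual-nearest one-to-one matching on centre distance.

    Candidate pairs are ranked by distance and accepted greedily, each index
    used at most once, and only if the distance is below
    ``max_dist_frac x reference radius``.  ``ref``/``test`` items need
    ``center_x_px``, ``center_y_px`` and ``diameter_px`` attributes.
    """
    candidates: list[tuple[float, int, int]] = []
    for i, r in enumerate(ref):
        gate = max_dist_frac * (r.diameter_px / 2.0)
        for j, t in enumerate(test):
            d = math.hypot(r.center_x_px - t.center_x_px,
                           r.center_y_px - t.center_y_px)
            if d < gate:
                candidates.append((d, i, j))
    candidates.sort()
    used_ref: set[int] = set()
    used_test: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for d, i, j in candidates:
        if i in used_ref or j in used_test:
            continue
        pairs.append((i, j, d))
        used_ref.add(i)
        used_test.add(j)
    return MatchResult(
        pairs=pairs,
        unmatched_ref=[i for i in range(len(ref)) if i not in used_ref],
        unmatched_test=[j for j in range(len(test)) if j not in used_test],
    )


@dataclass(frozen=True)
class EvaluationRecord:
    """Per-image detection/segmentation scores.

    ``detections_abs_err_um`` / ``detections_rel_err`` are NaN when no pair
    matched (they average over matched detections only).
    """

    dice: float
    iou: float
    pct_detection: float
    droplets_abs_err_um: float
    detections_abs_err_um: float
    detections_rel_err: float
    n_ref: int = 0
    n_test: int = 0


def _union_mask(dets: Sequence, shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    for d in dets:
        out |= rasterize_disk(shape, d.center_x_px, d.center_y_px,
                              d.diameter_px / 2.0)
    return out


def evaluate_detections(ref: Sequence, test: Sequence, um_per_px: float,
                        image_shape: tuple[int, int],
                        max_dist_frac: float = 0.5) -> EvaluationRecord:
    """Score a test detection set against a reference set from the same scene.

    Dice/IoU compare the unions of the rasterized detected disks.  An empty
    reference makes percentage detection undefined and raises rather than
    silently reporting 0.
    """
    if len(ref) == 0:
        raise ValueError("reference detection set is empty; "
                         "percentage detection undefined")
    match = match_detections(ref, test, max_dist_frac)

    pct = min(len(test) / len(ref), 1.0)

    d_test_for_ref = np.zeros(len(ref))
    for i, j, _ in match.pairs:
        d_test_for_ref[i] = test[j].diameter_um
    d_ref = np.array([r.diameter_um for r in ref])
    droplets_abs = float(np.mean(np.abs(d_ref - d_test_for_ref)))

    if match.pairs:
        abs_errs = [abs(ref[i].diameter_um - test[j].diameter_um)
                    for i, j, _ in match.pairs]
        rel_errs = [abs(ref[i].diameter_um - test[j].diameter_um)
                    / abs(ref[i].diameter_um) for i, j, _ in match.pairs]
        det_abs = float(np.mean(abs_errs))
        det_rel = float(np.mean(rel_errs))
    else:
        det_abs = math.nan
        det_rel = math.nan

    ref_mask = _union_mask(ref, image_shape)
    test_mask = _union_mask(test, image_shape)
    return EvaluationRecord(
        dice=dice(ref_mask, test_mask),
        iou=iou(ref_mask, test_mask),
        pct_detection=pct,
        droplets_abs_err_um=droplets_abs,
        detections_abs_err_um=det_abs,
        detections_rel_err=det_rel,
        n_ref=len(ref),
        n_test=len(test),
    )


def aggregate_records(records: Sequence[EvaluationRecord]) -> dict[str, tuple[float, float]]:
    """Mean ± standard deviation of every metric across a record set (NaNs from
    match-free images are ignored for the matched-only error columns)."""
    fields = ["dice", "iou", "pct_detection", "droplets_abs_err_um",
              "detections_abs_err_um", "detections_rel_err"]
    out: dict[str, tuple[float, float]] = {}
    for f in fields:
        vals = np.array([getattr(r, f) for r in records], dtype=np.float64)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            out[f] = (math.nan, math.nan)
        else:
            out[f] = (float(vals.mean()), float(vals.std()))
    return out
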