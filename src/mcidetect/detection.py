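"""Computer-vision tumor detection from score images.

The detection cascade has three steps:

1. **Clean** — glare removal (percentile-clipped pixels replaced by a
   local median), median noise filtering, min–max normalization to [0, 1]
   and optional contrast-limited histogram equalization.
2. **Segment** — a global threshold (Otsu by default) extracts the bright
   foreground; cascade filters suppress false positives (minimum
   connected-component area, border contact, low solidity); a
   Chan–Vese-style region-based active contour, initialized from the
   filtered mask with a fixed iteration cap, refines the boundary.
3. **Overlay** — the score image is rigidly registered to a synthesized
   RGB rendering by maximizing mutual information (32-bin joint
   histogram), and the detection mask is warped and alpha-blended onto
   the RGB image.

Detections are evaluated against ground truth with IOU (Jaccard index),
sensitivity, specificity and accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage, optimize
from skimage import exposure, measure
from skimage.filters import threshold_otsu
from skimage.segmentation import clear_border, morphological_chan_vese

from .hypercube import Hypercube
from .score_imaging import ScoreImage

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# RGB synthesis
# ---------------------------------------------------------------------------


@dataclass
class RGBImage:
    """8-bit color rendering of a hypercube with channel provenance."""

    values: np.ndarray  # (rows, cols, 3) uint8
    channel_wavelengths_nm: tuple[float, float, float]

    def intensity(self) -> np.ndarray:
        return self.values.astype(np.float64).mean(axis=2)


def synthesize_rgb(
    cube: Hypercube, rgb_nm: tuple[float, float, float] = (630.0, 532.0, 465.0)
) -> RGBImage:
    """Build an RGB image from the bands nearest the given R/G/B wavelengths.

    Each channel is min–max stretched to 8 bits independently; a constant
    channel renders mid-gray.
    """
    channels = []
    actual = []
    for nm in rgb_nm:
        try:
            idx = cube.band_index(nm)
        except ValueError as exc:
            raise ValueError(f"cube has no band near {nm} nm") from exc
        frame = cube.values[:, :, idx].astype(np.float64)
        lo, hi = float(frame.min()), float(frame.max())
        if hi > lo:
            chan = np.round((frame - lo) / (hi - lo) * 255).astype(np.uint8)
        else:
            chan = np.full(frame.shape, 127, dtype=np.uint8)
        channels.append(chan)
        actual.append(float(cube.wavelengths_nm[idx]))
    return RGBImage(
        values=np.stack(channels, axis=2),
        channel_wavelengths_nm=tuple(actual),
    )


# ---------------------------------------------------------------------------
# step 1: cleaning
# ---------------------------------------------------------------------------


@dataclass
class CleanConfig:
    glare_removal: bool = True
    glare_percentile: float = 99.5
    glare_window: int = 5
    median_filter: bool = True
    median_size: int = 3
    normalize: bool = True
    equalize: bool = False
    equalize_clip_limit: float = 0.01


def clean_score_image(score: ScoreImage, config: CleanConfig | None = None) -> ScoreImage:
    """Glare removal → median filter → min–max normalize → optional CLAHE.

    Each step can be toggled; with every step disabled the input values
    pass through unchanged.  Glare pixels (above the configured percentile
    or flagged invalid) are replaced by the median of a surrounding window.
    """
    config = config or CleanConfig()
    vals = score.values.astype(np.float64).copy()
    valid = score.valid_mask()

    if config.glare_removal:
        bad = ~valid
        if np.ptp(vals) > 0:
            cutoff = np.percentile(vals[valid] if valid.any() else vals,
                                   config.glare_percentile)
            bad = bad | (vals > cutoff)
        if bad.any():
            local_median = ndimage.median_filter(vals, size=config.glare_window)
            vals[bad] = local_median[bad]
    if config.median_filter:
        vals = ndimage.median_filter(vals, size=config.median_size)
    if config.normalize:
        lo, hi = float(vals.min()), float(vals.max())
        vals = (vals - lo) / (hi - lo) if hi > lo else np.zeros_like(vals)
    if config.equalize:
        vals = exposure.equalize_adapthist(
            np.clip(vals, 0.0, 1.0), clip_limit=config.equalize_clip_limit
        )
    return ScoreImage(
        values=vals,
        provenance=score.provenance,
        model_id=score.model_id,
        numerator_nm=score.numerator_nm,
        denominator_nm=score.denominator_nm,
        validity=None if score.validity is None else score.validity.copy(),
    )


# ---------------------------------------------------------------------------
# step 2: segmentation
# ---------------------------------------------------------------------------


@dataclass
class SegmentConfig:
    threshold: str | float = "otsu"  # "otsu" or a fixed value in [0, 1]
    min_area_fraction: float = 0.005
    remove_border_components: bool = True
    min_solidity: float = 0.5
    active_contour: bool = True
    contour_iterations: int = 200
    contour_smoothing: int = 1


@dataclass
class SegmentationResult:
    mask: np.ndarray
    empty: bool
    threshold_value: float
    stage_masks: dict = field(default_factory=dict)


def segment_detection(
    score: ScoreImage, config: SegmentConfig | None = None
) -> SegmentationResult:
    """Threshold → cascade filters → active-contour boundary refinement.

    An empty foreground after thresholding is not an error: the result
    carries an ``empty`` flag and an all-false mask.  The procedure is
    fully deterministic for a given configuration.
    """
    config = config or SegmentConfig()
    vals = score.values.astype(np.float64)

    if isinstance(config.threshold, str):
        if config.threshold != "otsu":
            raise ValueError(f"unknown threshold method {config.threshold!r}")
        if np.ptp(vals) == 0:
            return SegmentationResult(
                mask=np.zeros(vals.shape, dtype=bool),
                empty=True,
                threshold_value=float("nan"),
            )
        thr = float(threshold_otsu(vals))
    else:
        thr = float(config.threshold)
    fg = vals > thr
    stages = {"threshold": fg.copy()}

    # cascade filters
    min_area = max(1, int(round(config.min_area_fraction * vals.size)))
    labels = measure.label(fg, connectivity=2)
    filtered = np.zeros_like(fg)
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        if region.solidity < config.min_solidity:
            continue
        filtered[labels == region.label] = True
    if config.remove_border_components:
        filtered = clear_border(filtered)
    stages["filtered"] = filtered.copy()

    if not filtered.any():
        return SegmentationResult(
            mask=filtered, empty=True, threshold_value=thr, stage_masks=stages
        )

    mask = filtered
    if config.active_contour:
        refined = morphological_chan_vese(
            vals,
            num_iter=config.contour_iterations,
            init_level_set=filtered.astype(np.int8),
            smoothing=config.contour_smoothing,
        ).astype(bool)
        # the contour may flip phase or latch onto the dark region; keep the
        # orientation that overlaps the bright initialization
        if refined.any() and (refined & filtered).sum() < (~refined & filtered).sum():
            refined = ~refined
        if refined.any():
            mask = refined
        stages["contour"] = mask.copy()

    return SegmentationResult(
        mask=mask, empty=not mask.any(), threshold_value=thr, stage_masks=stages
    )


# ---------------------------------------------------------------------------
# step 3: registration and overlay
# ---------------------------------------------------------------------------


def _mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """Mutual information of two equally shaped images (joint histogram)."""
    hist, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    pxy = hist / hist.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))


def _warp(image: np.ndarray, params: np.ndarray, order: int = 1) -> np.ndarray:
    """Apply a rigid transform (dy, dx, theta_deg about the image center)."""
    dy, dx, theta_deg = params
    theta = np.deg2rad(theta_deg)
    center = (np.array(image.shape) - 1) / 2.0
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    offset = center - rot @ (center + np.array([dy, dx]))
    return ndimage.affine_transform(
        image, rot, offset=offset, order=order, mode="constant", cval=0.0
    )


@dataclass
class RegistrationConfig:
    bins: int = 32
    search_radius: int = 8
    refine_rotation: bool = True
    max_rotation_deg: float = 10.0


@dataclass
class RegistrationResult:
    shift: tuple[float, float]  # (dy, dx) applied to the moving image
    rotation_deg: float
    mutual_information: float
    converged: bool


class DetectionMetrics(NamedTuple):
    iou: float
    sensitivity: float
    specificity: float
    accuracy: float


@dataclass
class DetectionResult:
    """Binary tumor detection with overlay, metrics and audit artifacts."""

    mask: np.ndarray
    overlay: np.ndarray | None = None
    metrics: DetectionMetrics | None = None
    registration: RegistrationResult | None = None
    stage_artifacts: dict = field(default_factory=dict)


def register_images(
    moving: np.ndarray,
    fixed: np.ndarray,
    config: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Estimate a rigid transform aligning ``moving`` onto ``fixed``.

    Mutual information over a 32-bin joint histogram is maximized by a
    coarse integer-translation search followed by Powell refinement of
    (dy, dx, rotation) from the best coarse start.  A failed optimization
    falls back to the identity transform with a warning.
    """
    config = config or RegistrationConfig()
    moving = np.asarray(moving, dtype=np.float64)
    fixed = np.asarray(fixed, dtype=np.float64)
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed images must share a shape")

    ones = np.ones_like(moving)

    def negative_mi(params: np.ndarray) -> float:
        warped = _warp(moving, params)
        # restrict to the overlap region so border padding cannot inflate MI
        overlap = _warp(ones, params) > 0.5
        if overlap.sum() < 0.25 * overlap.size:
            return 0.0
        return -_mutual_information(warped[overlap], fixed[overlap], config.bins)

    r = config.search_radius
    best_params = np.zeros(3)
    best_val = negative_mi(best_params)
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            val = negative_mi(np.array([dy, dx, 0.0]))
            if val < best_val:
                best_val = val
                best_params = np.array([float(dy), float(dx), 0.0])

    converged = True
    try:
        bounds = [
            (best_params[0] - 2, best_params[0] + 2),
            (best_params[1] - 2, best_params[1] + 2),
            (-config.max_rotation_deg, config.max_rotation_deg)
            if config.refine_rotation
            else (0.0, 0.0),
        ]
        res = optimize.minimize(
            negative_mi,
            best_params,
            method="Powell",
            bounds=bounds,
            options={"xtol": 1e-3, "ftol": 1e-5, "maxiter": 200},
        )
        if res.fun <= best_val:
            best_params = res.x
            best_val = res.fun
        converged = bool(res.success)
    except Exception as exc:  # pragma: no cover - optimizer robustness
        logger.warning("registration optimizer failed (%s); using identity", exc)
        best_params = np.zeros(3)
        converged = False

    return RegistrationResult(
        shift=(float(best_params[0]), float(best_params[1])),
        rotation_deg=float(best_params[2]),
        mutual_information=-best_val,
        converged=converged,
    )


def register_overlay(
    score: ScoreImage | np.ndarray,
    rgb: RGBImage | np.ndarray,
    mask: np.ndarray | None = None,
    color: tuple[int, int, int] = (0, 255, 0),
    alpha: float = 0.5,
    config: RegistrationConfig | None = None,
) -> DetectionResult:
    """Register the score image to the RGB rendering and overlay the mask.

    The RGB image is collapsed to intensity for registration; the detection
    mask (default: the score thresholded at its midpoint when not given)
    is warped by the estimated rigid transform with nearest-neighbor
    interpolation and alpha-blended in ``color``.
    """
    score_vals = score.values if isinstance(score, ScoreImage) else np.asarray(score)
    rgb_vals = rgb.values if isinstance(rgb, RGBImage) else np.asarray(rgb)
    if rgb_vals.ndim != 3 or rgb_vals.shape[2] != 3:
        raise ValueError("rgb must be (rows, cols, 3)")
    intensity = rgb_vals.astype(np.float64).mean(axis=2)

    registration = register_images(score_vals, intensity, config)
    if mask is None:
        mask = score_vals > (score_vals.min() + np.ptp(score_vals) / 2.0)
    params = np.array([*registration.shift, registration.rotation_deg])
    warped = _warp(mask.astype(np.float64), params, order=0) > 0.5

    overlay = rgb_vals.astype(np.float64).copy()
    overlay[warped] = (1 - alpha) * overlay[warped] + alpha * np.asarray(color, float)
    return DetectionResult(
        mask=warped,
        overlay=np.round(np.clip(overlay, 0, 255)).astype(np.uint8),
        registration=registration,
    )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def evaluate_detection(mask: np.ndarray, truth: np.ndarray) -> DetectionMetrics:
    """IOU, sensitivity, specificity and accuracy of a binary detection.

    IOU = |mask ∩ truth| / |mask ∪ truth|, with IOU = 1 when both masks
    are empty.  Degenerate denominators (no positives / no negatives in
    truth) yield 1.0 for the corresponding rate.
    """
    mask = np.asarray(mask, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if mask.shape != truth.shape:
        raise ValueError("mask and truth shapes differ")
    tp = int(np.count_nonzero(mask & truth))
    fp = int(np.count_nonzero(mask & ~truth))
    fn = int(np.count_nonzero(~mask & truth))
    tn = int(np.count_nonzero(~mask & ~truth))
    union = tp + fp + fn
    iou = 1.0 if union == 0 else tp / union
    sensitivity = 1.0 if (tp + fn) == 0 else tp / (tp + fn)
    specificity = 1.0 if (tn + fp) == 0 else tn / (tn + fp)
    accuracy = (tp + tn) / mask.size if mask.size else 1.0
    return DetectionMetrics(
        iou=float(iou),
        sensitivity=float(sensitivity),
        specificity=float(specificity),
        accuracy=float(accuracy),
    )


def detect_tumor(
    score: ScoreImage,
    rgb: RGBImage | None = None,
    truth: np.ndarray | None = None,
    clean_config: CleanConfig | None = None,
    segment_config: SegmentConfig | None = None,
    registration_config: RegistrationConfig | None = None,
    color: tuple[int, int, int] = (0, 255, 0),
    alpha: float = 0.5,
) -> DetectionResult:
    """Run the full cascade: clean → segment → (overlay) → (evaluate)."""
    cleaned = clean_score_image(score, clean_config)
    segmentation = segment_detection(cleaned, segment_config)
    result = DetectionResult(
        mask=segmentation.mask,
        stage_artifacts={
            "cleaned_score": cleaned.values,
            **segmentation.stage_masks,
        },
    )
    if rgb is not None:
        overlaid = register_overlay(
            cleaned, rgb, mask=segmentation.mask, color=color, alpha=alpha,
            config=registration_config,
        )
        result.overlay = overlaid.overlay
        result.registration = overlaid.registration
        result.mask = overlaid.mask
    if truth is not None:
        result.metrics = evaluate_detection(result.mask, truth)
    return result
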