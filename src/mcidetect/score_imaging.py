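"""Tumor score images: model-based and ratiometric, with evaluation.

A *score image* collapses a hypercube into a single frame in which pixels
of the target tissue (tumor) are brighter than the background.  Two
routes are implemented:

* **Multivariate** — apply a fitted binary PLS-DA model to every pixel
  spectrum (vector-normalized absorbance); the pixel value is the model's
  tumor probability.
* **Ratiometric** — divide one corrected reflectance frame by another.
  Choosing the numerator where the target absorbs *less* than the
  background and the denominator where it absorbs *more* makes the target
  bright; only two wavelength frames are needed, which is what makes this
  route real-time capable.

Wavelength pairs can be selected per specimen or as a *consistent case*
pair that maximizes the worst-case contrast across several specimens.
Score images are evaluated by SNR — (mean target − mean background) /
background standard deviation — and by pixelwise AUROC against the
ground-truth mask.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import tifffile
from scipy.stats import rankdata

from .chemometrics import BINARY, PLSDAModel, compute_roc
from .hypercube import Hypercube, LabelMask, REFLECTANCE, ABSORBANCE

#: Name reserved for non-tissue scene background in a LabelMask; excluded
#: from both target and background pixel sets during evaluation/selection.
SCENE_BACKGROUND = "background"


@dataclass
class ScoreImage:
    """Single-frame tumor-contrast image with provenance and validity."""

    values: np.ndarray
    provenance: str  # "plsda" | "ratiometric"
    model_id: str | None = None
    numerator_nm: float | None = None
    denominator_nm: float | None = None
    validity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("score image must be 2-D")
        if self.validity is not None:
            self.validity = np.asarray(self.validity, dtype=bool)
            if self.validity.shape != self.values.shape:
                raise ValueError("validity mask shape mismatch")

    def valid_mask(self) -> np.ndarray:
        if self.validity is None:
            return np.ones(self.values.shape, dtype=bool)
        return self.validity

    def save(self, path) -> Path:
        """Write a 16-bit TIFF plus a JSON sidecar with provenance."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        vals = self.values.copy()
        valid = self.valid_mask()
        finite = vals[valid]
        lo = float(finite.min()) if finite.size else 0.0
        hi = float(finite.max()) if finite.size else 1.0
        scaled = (vals - lo) / (hi - lo) if hi > lo else np.zeros_like(vals)
        scaled[~valid] = 0.0
        tifffile.imwrite(path, np.round(np.clip(scaled, 0, 1) * 65535).astype(np.uint16))
        sidecar = {
            "provenance": self.provenance,
            "model_id": self.model_id,
            "numerator_nm": self.numerator_nm,
            "denominator_nm": self.denominator_nm,
            "display_range": [lo, hi],
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
        return path


@dataclass(frozen=True)
class WavelengthPair:
    """An ordered ratiometric pair with its achieved contrast score."""

    numerator_nm: float
    denominator_nm: float
    contrast_score: float = float("nan")
    scope: str = "single_specimen"  # or "consistent_case"

    def __post_init__(self) -> None:
        if self.numerator_nm == self.denominator_nm:
            raise ValueError("numerator and denominator wavelengths must differ")


class ScoreEvaluation(NamedTuple):
    snr: float
    auroc: float


# ---------------------------------------------------------------------------
# score image generation
# ---------------------------------------------------------------------------


def plsda_score_image(cube: Hypercube, model: PLSDAModel) -> ScoreImage:
    """Per-pixel tumor probability from a binary PLS-DA model.

    The cube must already be corrected, converted to absorbance, and
    cropped to the model's training axis; pixel spectra are
    vector-normalized here before scoring.
    """
    if model.mode != BINARY:
        raise ValueError("plsda_score_image requires a binary model")
    if cube.mode != ABSORBANCE:
        raise ValueError("expected an absorbance-mode cube")
    if not np.array_equal(cube.wavelengths_nm, model.wavelengths_nm):
        raise ValueError("cube wavelength axis differs from the model's training axis")
    rows, cols = cube.spatial_shape
    flat = cube.values.reshape(-1, cube.n_bands)
    norms = np.linalg.norm(flat, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    scores = model.predict_proba(flat / safe[:, None])
    values = scores.reshape(rows, cols)
    validity = cube.valid_mask() & (norms.reshape(rows, cols) > 0)
    return ScoreImage(
        values=values,
        provenance="plsda",
        model_id=f"plsda:{model.positive_class}:{model.n_factors}f",
        validity=validity,
    )


def ratiometric_score_image(
    cube: Hypercube,
    pair: WavelengthPair | tuple[float, float],
    epsilon: float = 1e-8,
) -> ScoreImage:
    """Divide the numerator wavelength frame by the denominator frame.

    Operates on a corrected reflectance cube with nearest-band matching;
    pixels whose denominator is ≤ ``epsilon`` are flagged invalid.
    """
    if cube.mode != REFLECTANCE:
        raise ValueError("ratiometric score images are computed on reflectance cubes")
    if not isinstance(pair, WavelengthPair):
        pair = WavelengthPair(*pair)
    num = cube.frame(pair.numerator_nm)
    den = cube.frame(pair.denominator_nm)
    bad = den <= epsilon
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(bad, 0.0, num / np.where(bad, 1.0, den))
    return ScoreImage(
        values=ratio,
        provenance="ratiometric",
        numerator_nm=float(cube.wavelengths_nm[cube.band_index(pair.numerator_nm)]),
        denominator_nm=float(cube.wavelengths_nm[cube.band_index(pair.denominator_nm)]),
        validity=cube.valid_mask() & ~bad,
    )


# ---------------------------------------------------------------------------
# wavelength-pair selection
# ---------------------------------------------------------------------------


def _pair_auroc_matrix(
    reflectance: np.ndarray, is_target: np.ndarray
) -> np.ndarray:
    """AUROC of the ratio band_i / band_j for every ordered pair (i, j).

    Uses the rank (Mann–Whitney) identity: AUROC = (R+ − n+(n+ + 1)/2) /
    (n+ · n−) where R+ is the rank sum of target pixels, with midranks for
    ties — identical to trapezoidal integration of the empirical ROC.
    """
    n_pix, n_bands = reflectance.shape
    n_pos = int(is_target.sum())
    n_neg = n_pix - n_pos
    out = np.full((n_bands, n_bands), np.nan)
    for j in range(n_bands):
        den = reflectance[:, j]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = reflectance / den[:, None]
        ranks = rankdata(ratios, axis=0)
        pos_rank_sum = ranks[is_target].sum(axis=0)
        auc = (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
        out[:, j] = auc
        out[j, j] = np.nan
    return out


def select_wavelength_pair(
    cubes: Sequence[tuple[Hypercube, LabelMask]],
    target_class: str = "tumor",
    scope: str = "consistent_case",
    max_pixels_per_cube: int = 4000,
    seed: int = 0,
    epsilon: float = 1e-8,
) -> WavelengthPair:
    """Exhaustive search over all ordered on-axis wavelength pairs.

    For each corrected reflectance cube, candidate contrast is the
    score-image AUROC of target vs background pixels (background = union
    of all non-target tissue classes; a class literally named
    ``"background"`` is treated as non-tissue and excluded).
    ``single_specimen`` maximizes the (first) cube's AUROC;
    ``consistent_case`` maximizes the minimum AUROC across cubes, breaking
    ties by higher mean and then lower numerator wavelength.
    """
    if not cubes:
        raise ValueError("need at least one (cube, mask) pair")
    if scope not in ("single_specimen", "consistent_case"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope == "single_specimen":
        cubes = cubes[:1]
    rng = np.random.default_rng(seed)
    wl = cubes[0][0].wavelengths_nm
    per_cube = []
    for cube, mask in cubes:
        if cube.mode != REFLECTANCE:
            raise ValueError("pair selection runs on corrected reflectance cubes")
        if not np.array_equal(cube.wavelengths_nm, wl):
            raise ValueError("all cubes must share one wavelength axis")
        if mask.shape != cube.spatial_shape:
            raise ValueError("mask shape mismatch")
        target = mask.class_mask(target_class)
        tissue = np.ones(mask.shape, dtype=bool)
        if SCENE_BACKGROUND in mask.class_names:
            tissue &= ~mask.class_mask(SCENE_BACKGROUND)
        usable = tissue & cube.valid_mask()
        usable &= np.all(cube.values > epsilon, axis=2)
        tgt_idx = np.flatnonzero((target & usable).ravel())
        bkg_idx = np.flatnonzero((~target & usable).ravel())
        if tgt_idx.size == 0 or bkg_idx.size == 0:
            raise ValueError("cube lacks usable target or background pixels")
        half = max_pixels_per_cube // 2
        if tgt_idx.size > half:
            tgt_idx = rng.choice(tgt_idx, size=half, replace=False)
        if bkg_idx.size > half:
            bkg_idx = rng.choice(bkg_idx, size=half, replace=False)
        idx = np.concatenate([tgt_idx, bkg_idx])
        flat = cube.values.reshape(-1, cube.n_bands)[idx]
        is_target = np.zeros(idx.size, dtype=bool)
        is_target[: tgt_idx.size] = True
        per_cube.append(_pair_auroc_matrix(flat, is_target))

    stack = np.stack(per_cube)  # (n_cubes, nb, nb)
    if np.all(np.isnan(stack)):
        raise ValueError("no valid wavelength pair")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # NaN diagonal
        objective = np.nanmin(stack, axis=0)
        mean_obj = np.nanmean(stack, axis=0)

    flat_obj = np.where(np.isnan(objective), -np.inf, objective)
    best = flat_obj.max()
    ties = np.argwhere(np.isclose(flat_obj, best, rtol=0, atol=1e-12))
    # ties → higher mean, then lower numerator wavelength
    tie_mean = mean_obj[ties[:, 0], ties[:, 1]]
    keep = ties[np.isclose(tie_mean, tie_mean.max(), rtol=0, atol=1e-12)]
    keep = keep[np.lexsort((wl[keep[:, 1]], wl[keep[:, 0]]))]
    i, j = keep[0]
    return WavelengthPair(
        numerator_nm=float(wl[i]),
        denominator_nm=float(wl[j]),
        contrast_score=float(objective[i, j]),
        scope=scope,
    )


def pair_search_table(
    cubes: Sequence[tuple[Hypercube, LabelMask]],
    target_class: str = "tumor",
    max_pixels_per_cube: int = 4000,
    seed: int = 0,
):
    """Full pair-search results as a DataFrame (per-cube and aggregate AUROC)."""
    import pandas as pd

    wl = cubes[0][0].wavelengths_nm
    mats = []
    for k, (cube, mask) in enumerate(cubes):
        target = mask.class_mask(target_class)
        usable = cube.valid_mask() & np.all(cube.values > 1e-8, axis=2)
        if SCENE_BACKGROUND in mask.class_names:
            usable &= ~mask.class_mask(SCENE_BACKGROUND)
        tgt = np.flatnonzero((target & usable).ravel())
        bkg = np.flatnonzero((~target & usable).ravel())
        half = max_pixels_per_cube // 2
        sub_rng = np.random.default_rng(seed + k)
        if tgt.size > half:
            tgt = sub_rng.choice(tgt, size=half, replace=False)
        if bkg.size > half:
            bkg = sub_rng.choice(bkg, size=half, replace=False)
        idx = np.concatenate([tgt, bkg])
        flat = cube.values.reshape(-1, cube.n_bands)[idx]
        is_target = np.zeros(idx.size, dtype=bool)
        is_target[: tgt.size] = True
        mats.append(_pair_auroc_matrix(flat, is_target))
    stack = np.stack(mats)
    nb = wl.size
    ii, jj = np.meshgrid(np.arange(nb), np.arange(nb), indexing="ij")
    keep = ii != jj
    data = {
        "numerator_nm": wl[ii[keep]],
        "denominator_nm": wl[jj[keep]],
        "min_auroc": np.nanmin(stack, axis=0)[keep],
        "mean_auroc": np.nanmean(stack, axis=0)[keep],
    }
    for k in range(len(cubes)):
        data[f"auroc_cube{k}"] = stack[k][keep]
    return pd.DataFrame(data).sort_values("min_auroc", ascending=False)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def evaluate_score_image(
    score: ScoreImage,
    truth: LabelMask,
    target_class: str = "tumor",
) -> ScoreEvaluation:
    """SNR and pixelwise AUROC of a score image against ground truth.

    SNR = (mean target − mean background) / background standard deviation
    (population formula); background = all labeled non-target tissue
    pixels, excluding a class named ``"background"`` and invalid pixels.
    """
    if truth.shape != score.values.shape:
        raise ValueError("label mask shape does not match score image")
    valid = score.valid_mask()
    target = truth.class_mask(target_class) & valid
    background = ~truth.class_mask(target_class) & valid
    if SCENE_BACKGROUND in truth.class_names:
        background &= ~truth.class_mask(SCENE_BACKGROUND)
    if not target.any() or not background.any():
        raise ValueError("target and background pixel sets must be nonempty")
    t_vals = score.values[target]
    b_vals = score.values[background]
    b_sd = float(b_vals.std(ddof=0))
    diff = float(t_vals.mean() - b_vals.mean())
    if b_sd == 0:
        # a constant background with separated means is infinite contrast;
        # with equal means the ratio is 0/0 and genuinely undefined
        if diff == 0:
            raise ValueError("background has zero variance; SNR undefined")
        snr = float(np.inf) if diff > 0 else float(-np.inf)
    else:
        snr = diff / b_sd
    scores = np.concatenate([t_vals, b_vals])
    labels = np.concatenate([np.ones(t_vals.size), np.zeros(b_vals.size)])
    auroc = compute_roc(scores, labels).auroc
    return ScoreEvaluation(snr=snr, auroc=float(auroc))
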