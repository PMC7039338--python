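"""Hypercube data model and Vis-NIR preprocessing.

A molecular chemical image ("hypercube") stacks wavelength-resolved
reflectance frames into a 3-D array indexed ``(row, col, band)``.  Each
pixel carries a full diffuse-reflectance spectrum determined by the
molecular composition of the tissue at that location.  This module holds
the in-memory containers (:class:`Hypercube`, :class:`LabelMask`,
:class:`SpectrumSet`) and the standard preprocessing chain applied before
any chemometric analysis:

1. instrument-response correction against a reflectance standard,
2. conversion from reflectance to absorbance, ``A = log10(1/R)``,
3. spectral cropping to the analysis window,
4. ROI-averaged signature extraction,
5. vector (Euclidean) normalization of signatures.

All masks and images use (row, col) indexing, 0-based, origin top-left.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REFLECTANCE = "reflectance"
ABSORBANCE = "absorbance"

#: Sentinel stored at pixels invalidated during correction.
INVALID_SENTINEL = 0.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class Hypercube:
    """A 3-D spectral image: ``values[row, col, band]`` with a wavelength axis.

    Parameters
    ----------
    values
        Array of shape ``(rows, cols, bands)``.  Nonnegative in
        reflectance mode.
    wavelengths_nm
        Strictly increasing wavelength per band, in nanometres.
    mode
        ``"reflectance"`` or ``"absorbance"``.
    pixel_size_mm
        Optional physical pixel pitch.
    field_of_view_id
        Free-text identifier of the acquisition (one hypercube = one FOV).
    validity
        Optional boolean mask of shape ``(rows, cols)``; ``False`` marks
        pixels invalidated during preprocessing (e.g. zero reference).
    """

    values: np.ndarray
    wavelengths_nm: np.ndarray
    mode: str = REFLECTANCE
    pixel_size_mm: float | None = None
    field_of_view_id: str = ""
    validity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("hypercube values must be 3-D (row, col, band)")
        if self.values.shape[2] != self.wavelengths_nm.size:
            raise ValueError(
                f"band count {self.values.shape[2]} does not match "
                f"{self.wavelengths_nm.size} wavelengths"
            )
        if self.wavelengths_nm.size and np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.mode not in (REFLECTANCE, ABSORBANCE):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == REFLECTANCE and self.values.size and self.values.min() < 0:
            raise ValueError("reflectance values must be nonnegative")
        if self.pixel_size_mm is not None and self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")
        if self.validity is not None:
            self.validity = np.asarray(self.validity, dtype=bool)
            if self.validity.shape != self.spatial_shape:
                raise ValueError("validity mask shape must match spatial grid")

    # -- basic geometry -----------------------------------------------------

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def band_step_nm(self) -> float:
        """Median band spacing (5 nm for the standard 400–1100 nm axis)."""
        if self.n_bands < 2:
            return np.inf
        return float(np.median(np.diff(self.wavelengths_nm)))

    def band_index(self, nm: float) -> int:
        """Index of the band nearest ``nm``; error beyond half a band step."""
        idx = int(np.argmin(np.abs(self.wavelengths_nm - nm)))
        half_step = self.band_step_nm() / 2.0
        if abs(self.wavelengths_nm[idx] - nm) > half_step + 1e-9:
            raise ValueError(
                f"{nm} nm is off the wavelength axis "
                f"(nearest band {self.wavelengths_nm[idx]} nm)"
            )
        return idx

    def frame(self, nm: float) -> np.ndarray:
        """Single wavelength-resolved image frame nearest ``nm``."""
        return self.values[:, :, self.band_index(nm)]

    def valid_mask(self) -> np.ndarray:
        if self.validity is None:
            return np.ones(self.spatial_shape, dtype=bool)
        return self.validity


@dataclass
class LabelMask:
    """Per-pixel tissue ground truth on the hypercube's spatial grid."""

    labels: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        if self.labels.size:
            lo, hi = int(self.labels.min()), int(self.labels.max())
            if lo < 0 or hi >= len(self.class_names):
                raise ValueError("label values must index into class_names")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_index(self, name: str) -> int:
        try:
            return self.class_names.index(name)
        except ValueError:
            raise KeyError(f"unknown tissue class {name!r}") from None

    def class_mask(self, name: str) -> np.ndarray:
        return self.labels == self.class_index(name)

    def class_counts(self) -> dict[str, int]:
        return {
            name: int(np.count_nonzero(self.labels == i))
            for i, name in enumerate(self.class_names)
        }


@dataclass
class SpectrumSet:
    """Labeled signature spectra sharing one wavelength axis.

    ``values`` has shape ``(n_spectra, n_bands)``; per-spectrum metadata is
    carried in parallel lists.  Spectra averaged over an ROI and tagged with
    tissue class and field of view are termed *signatures*.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    tissue_class: list[str]
    field_of_view_id: list[str]
    roi_id: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=np.float64)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        n = self.values.shape[0]
        if self.values.shape[1] != self.wavelengths_nm.size:
            raise ValueError("spectrum length does not match wavelength axis")
        for name, meta in (
            ("tissue_class", self.tissue_class),
            ("field_of_view_id", self.field_of_view_id),
            ("roi_id", self.roi_id),
        ):
            if len(meta) != n:
                raise ValueError(f"{name} must have one entry per spectrum")
        if self.normalized and n:
            norms = np.linalg.norm(self.values, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("normalized=True but spectra are not unit-norm")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.tissue_class:
            seen.setdefault(c)
        return list(seen)

    def groups(self) -> list[str]:
        """Tissue-class × field-of-view grouping key per spectrum."""
        return [f"{c}|{f}" for c, f in zip(self.tissue_class, self.field_of_view_id)]

    def subset(self, idx: Sequence[int] | np.ndarray) -> "SpectrumSet":
        idx = np.asarray(idx)
        return SpectrumSet(
            wavelengths_nm=self.wavelengths_nm,
            values=self.values[idx],
            tissue_class=[self.tissue_class[i] for i in idx],
            field_of_view_id=[self.field_of_view_id[i] for i in idx],
            roi_id=[self.roi_id[i] for i in idx],
            normalized=self.normalized,
        )

    def class_mean(self, name: str) -> np.ndarray:
        sel = [i for i, c in enumerate(self.tissue_class) if c == name]
        if not sel:
            raise KeyError(f"no spectra for class {name!r}")
        return self.values[sel].mean(axis=0)

    # -- CSV round trip -----------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"{w:g}" for w in self.wavelengths_nm])
        df.insert(0, "roi_id", self.roi_id)
        df.insert(0, "field_of_view_id", self.field_of_view_id)
        df.insert(0, "tissue_class", self.tissue_class)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, normalized: bool = False) -> "SpectrumSet":
        df = pd.read_csv(path)
        meta_cols = ["tissue_class", "field_of_view_id", "roi_id"]
        wl_cols = [c for c in df.columns if c not in meta_cols]
        return cls(
            wavelengths_nm=np.array([float(c) for c in wl_cols]),
            values=df[wl_cols].to_numpy(dtype=np.float64),
            tissue_class=df["tissue_class"].astype(str).tolist(),
            field_of_view_id=df["field_of_view_id"].astype(str).tolist(),
            roi_id=df["roi_id"].astype(str).tolist(),
            normalized=normalized,
        )


def concat_spectra(sets: Iterable[SpectrumSet]) -> SpectrumSet:
    """Stack SpectrumSets sharing a wavelength axis into one set."""
    sets = list(sets)
    if not sets:
        raise ValueError("no SpectrumSets to concatenate")
    wl = sets[0].wavelengths_nm
    for s in sets[1:]:
        if not np.array_equal(s.wavelengths_nm, wl):
            raise ValueError("wavelength axes differ between SpectrumSets")
    if len({s.normalized for s in sets}) != 1:
        raise ValueError("cannot mix normalized and unnormalized SpectrumSets")
    return SpectrumSet(
        wavelengths_nm=wl,
        values=np.vstack([s.values for s in sets]),
        tissue_class=sum((s.tissue_class for s in sets), []),
        field_of_view_id=sum((s.field_of_view_id for s in sets), []),
        roi_id=sum((s.roi_id for s in sets), []),
        normalized=sets[0].normalized,
    )


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------


def correct_instrument_response(
    raw: Hypercube,
    reference: Hypercube,
    standard_reflectance: float = 0.99,
    epsilon: float = 1e-8,
) -> Hypercube:
    """Divide a raw hypercube by a reflectance-standard hypercube.

    The quotient removes the wavelength-dependent instrument/illumination
    response.  Because the standard itself reflects only
    ``standard_reflectance`` (99% for the usual Spectralon panel), the
    quotient is rescaled by that factor so the output is absolute
    reflectance.  Pixels where the reference drops below ``epsilon`` at any
    band are set to a sentinel and flagged in the validity mask.
    """
    if raw.mode != REFLECTANCE or reference.mode != REFLECTANCE:
        raise ValueError("both cubes must be in reflectance mode")
    if raw.values.shape != reference.values.shape or not np.array_equal(
        raw.wavelengths_nm, reference.wavelengths_nm
    ):
        raise ValueError("raw and reference cubes must share shape and wavelength axis")

    bad = np.any(reference.values <= epsilon, axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = raw.values / reference.values * standard_reflectance
    corrected[bad] = INVALID_SENTINEL
    validity = raw.valid_mask() & ~bad
    return Hypercube(
        values=corrected,
        wavelengths_nm=raw.wavelengths_nm.copy(),
        mode=REFLECTANCE,
        pixel_size_mm=raw.pixel_size_mm,
        field_of_view_id=raw.field_of_view_id,
        validity=validity,
    )


def reflectance_to_absorbance(cube: Hypercube, floor: float = 1e-6) -> Hypercube:
    """Convert reflectance to absorbance, ``A = log10(1 / R)``.

    Reflectance values at or below ``floor`` are clamped to ``floor``
    before the logarithm (so ``R = 0`` maps to a large, finite absorbance)
    and a warning is logged.
    """
    if cube.mode != REFLECTANCE:
        raise ValueError("input cube is already in absorbance mode")
    r = cube.values
    n_clamped = int(np.count_nonzero(r <= floor))
    if n_clamped:
        logger.warning(
            "reflectance_to_absorbance: clamped %d values at floor %g",
            n_clamped,
            floor,
        )
    a = -np.log10(np.maximum(r, floor))
    return Hypercube(
        values=a,
        wavelengths_nm=cube.wavelengths_nm.copy(),
        mode=ABSORBANCE,
        pixel_size_mm=cube.pixel_size_mm,
        field_of_view_id=cube.field_of_view_id,
        validity=None if cube.validity is None else cube.validity.copy(),
    )


def crop_spectral_range(item, lo_nm: float, hi_nm: float):
    """Retain bands with ``lo_nm <= λ <= hi_nm`` (closed interval).

    Works on :class:`Hypercube` and :class:`SpectrumSet`; band order is
    preserved and an empty result is an error.  The standard analysis
    window 520–1050 nm reduces the 141-band 400–1100 nm axis to 107 bands.
    """
    if lo_nm >= hi_nm:
        raise ValueError("lo_nm must be smaller than hi_nm")
    wl = item.wavelengths_nm
    keep = (wl >= lo_nm) & (wl <= hi_nm)
    if not keep.any():
        raise ValueError(f"no bands in [{lo_nm}, {hi_nm}] nm")
    if isinstance(item, Hypercube):
        return replace(
            item,
            values=item.values[:, :, keep],
            wavelengths_nm=wl[keep],
            validity=None if item.validity is None else item.validity.copy(),
        )
    if isinstance(item, SpectrumSet):
        out = SpectrumSet(
            wavelengths_nm=wl[keep],
            values=item.values[:, keep],
            tissue_class=list(item.tissue_class),
            field_of_view_id=list(item.field_of_view_id),
            roi_id=list(item.roi_id),
            normalized=False,
        )
        return out
    raise TypeError(f"cannot crop object of type {type(item).__name__}")


def extract_roi_spectra(
    cube: Hypercube,
    mask: LabelMask,
    rois_per_class: int = 10,
    roi_shape: tuple[int, int] = (3, 3),
    seed: int = 0,
    classes: Sequence[str] | None = None,
    exclude_invalid: bool = True,
) -> SpectrumSet:
    """Average rectangular ROIs into one signature spectrum each.

    For every requested tissue class, ``rois_per_class`` non-overlapping
    ``roi_shape`` rectangles are placed uniformly at random (seeded),
    wholly inside that class's labeled pixels; each output spectrum is the
    unweighted mean of the pixel spectra in one ROI.  Output is *not*
    vector-normalized.
    """
    if mask.shape != cube.spatial_shape:
        raise ValueError("label mask shape does not match hypercube spatial grid")
    rng = np.random.default_rng(seed)
    rr, rc = roi_shape
    if rr < 1 or rc < 1:
        raise ValueError("roi_shape entries must be positive")
    wanted = list(classes) if classes is not None else list(mask.class_names)

    valid = cube.valid_mask()
    rows, cols = cube.spatial_shape
    spectra, klass, fovs, rois = [], [], [], []
    for name in wanted:
        cls = mask.class_mask(name)
        if exclude_invalid:
            cls = cls & valid
        # valid top-left corners: the whole rectangle lies in the class
        ok = np.zeros((rows - rr + 1, cols - rc + 1), dtype=bool)
        if ok.size:
            window = np.lib.stride_tricks.sliding_window_view(cls, (rr, rc))
            ok = window.all(axis=(2, 3))
        candidates = np.argwhere(ok)
        if candidates.shape[0] == 0:
            raise ValueError(
                f"class {name!r} has too few pixels for a {rr}x{rc} ROI"
            )
        order = rng.permutation(candidates.shape[0])
        occupied = np.zeros((rows, cols), dtype=bool)
        placed = 0
        for k in order:
            r0, c0 = candidates[k]
            if occupied[r0 : r0 + rr, c0 : c0 + rc].any():
                continue
            occupied[r0 : r0 + rr, c0 : c0 + rc] = True
            block = cube.values[r0 : r0 + rr, c0 : c0 + rc, :]
            spectra.append(block.reshape(-1, cube.n_bands).mean(axis=0))
            klass.append(name)
            fovs.append(cube.field_of_view_id)
            rois.append(f"{name}-{placed:02d}@{r0},{c0}")
            placed += 1
            if placed == rois_per_class:
                break
        if placed < rois_per_class:
            raise ValueError(
                f"class {name!r}: only {placed} of {rois_per_class} "
                f"non-overlapping {rr}x{rc} ROIs could be placed"
            )
    return SpectrumSet(
        wavelengths_nm=cube.wavelengths_nm.copy(),
        values=np.vstack(spectra),
        tissue_class=klass,
        field_of_view_id=fovs,
        roi_id=rois,
        normalized=False,
    )


def vector_normalize(spectra: SpectrumSet) -> SpectrumSet:
    """Scale every spectrum to unit Euclidean norm."""
    norms = np.linalg.norm(spectra.values, axis=1)
    if np.any(norms == 0):
        raise ValueError("cannot vector-normalize an all-zero spectrum")
    return SpectrumSet(
        wavelengths_nm=spectra.wavelengths_nm.copy(),
        values=spectra.values / norms[:, None],
        tissue_class=list(spectra.tissue_class),
        field_of_view_id=list(spectra.field_of_view_id),
        roi_id=list(spectra.roi_id),
        normalized=True,
    )
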