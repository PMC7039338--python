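"""Synthetic Vis-NIR tissue phantoms with known ground truth.

The generator emulates the diffuse-reflectance phenomenology of kidney
tissue in the 400–1100 nm window: absorbance spectra are additive Gaussian
mixtures of chromophore components — oxygenated hemoglobin (peaks at 545
and 575 nm), deoxygenated hemoglobin (755 nm), lipid (930 nm) and water
(965 nm) — on a per-tissue baseline.  Tumor carries the highest water
weight, fat and renal sinus fat (RSF) the highest lipid weights, and
normal renal parenchyma (NRP) is the most blood-rich, mirroring the
relative peak intensities reported for these tissues.

A phantom scene paints tissue regions onto a grid, synthesizes a per-pixel
absorbance spectrum with lognormal weight jitter, inverts to reflectance
(``R = 10^(-A)``), multiplies by a smooth instrument-response curve, and
degrades with truncated Gaussian noise and clustered glare (near-saturation
specular highlights).  A matching 99%-reflectance-standard cube is produced
with the same instrument response so the full preprocessing chain can be
exercised and, in the noise-free case, inverted exactly.

What the phantoms do *not* emulate: photon transport (scattering
anisotropy, depth-resolved obscuration), tumor heterogeneity/necrosis, and
inter-patient signature variability beyond weight jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hypercube import Hypercube, LabelMask, REFLECTANCE

DEFAULT_WAVELENGTHS_NM = np.arange(400.0, 1100.0 + 1e-9, 5.0)  # 141 bands


# ---------------------------------------------------------------------------
# spectral building blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AbsorptionComponent:
    """A chromophore: a named sum of Gaussian absorption peaks.

    ``peaks`` is a list of ``(center_nm, width_nm, relative_height)``;
    widths are Gaussian sigmas in nm.
    """

    name: str
    peaks: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        for center, width, height in self.peaks:
            if width <= 0:
                raise ValueError(f"component {self.name!r}: peak width must be > 0")
            if height < 0:
                raise ValueError(f"component {self.name!r}: peak height must be >= 0")

    def evaluate(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths_nm, dtype=np.float64)
        out = np.zeros_like(wl)
        for center, width, height in self.peaks:
            out += height * np.exp(-((wl - center) ** 2) / (2.0 * width**2))
        return out


def default_component_library() -> list[AbsorptionComponent]:
    """The five-chromophore library behind all default tissue recipes."""
    return [
        AbsorptionComponent(
            "oxyhemoglobin", ((545.0, 13.0, 1.0), (575.0, 13.0, 0.95))
        ),
        AbsorptionComponent("deoxyhemoglobin", ((755.0, 30.0, 1.0),)),
        AbsorptionComponent("lipid", ((930.0, 22.0, 1.0),)),
        AbsorptionComponent("water", ((965.0, 28.0, 1.0),)),
    ]


@dataclass(frozen=True)
class TissueRecipe:
    """Component weights + baseline defining one tissue's absorbance.

    ``weight_cv`` is the coefficient of variation of the per-pixel
    lognormal jitter applied to each component weight when a phantom is
    rendered (0 disables jitter).
    """

    tissue_class: str
    component_weights: dict[str, float]
    baseline_absorbance: float = 0.2
    weight_cv: float = 0.05

    def __post_init__(self) -> None:
        if not any(w > 0 for w in self.component_weights.values()):
            raise ValueError(
                f"recipe {self.tissue_class!r} needs at least one positive weight"
            )


def default_tissue_recipes() -> dict[str, TissueRecipe]:
    """Kidney-specimen recipes: tumor water-rich, fat/RSF lipid-rich, NRP blood-rich."""
    return {
        "tumor": TissueRecipe(
            "tumor",
            {"oxyhemoglobin": 0.25, "deoxyhemoglobin": 0.10, "lipid": 0.05, "water": 0.45},
            baseline_absorbance=0.25,
        ),
        "NRP": TissueRecipe(
            "NRP",
            {"oxyhemoglobin": 0.45, "deoxyhemoglobin": 0.15, "lipid": 0.08, "water": 0.18},
            baseline_absorbance=0.22,
        ),
        "fat": TissueRecipe(
            "fat",
            {"oxyhemoglobin": 0.10, "deoxyhemoglobin": 0.03, "lipid": 0.50, "water": 0.08},
            baseline_absorbance=0.18,
        ),
        "RSF": TissueRecipe(
            "RSF",
            {"oxyhemoglobin": 0.12, "deoxyhemoglobin": 0.04, "lipid": 0.46, "water": 0.10},
            baseline_absorbance=0.18,
        ),
    }


def synthesize_signature(
    recipe: TissueRecipe,
    wavelengths_nm: np.ndarray,
    library: Sequence[AbsorptionComponent] | None = None,
) -> np.ndarray:
    """Noise-free absorbance spectrum for a recipe on a wavelength axis."""
    wl = np.asarray(wavelengths_nm, dtype=np.float64)
    if wl.size == 0:
        raise ValueError("wavelength axis is empty")
    lib = {c.name: c for c in (library or default_component_library())}
    out = np.full(wl.shape, float(recipe.baseline_absorbance))
    for name, weight in recipe.component_weights.items():
        if weight < 0:
            raise ValueError(f"negative weight for component {name!r}")
        if weight == 0:
            continue
        if name not in lib:
            raise KeyError(f"unknown absorption component {name!r}")
        out += weight * lib[name].evaluate(wl)
    return out


def instrument_response(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Smooth, strictly positive lamp/filter/detector response (raised cosine)."""
    wl = np.asarray(wavelengths_nm, dtype=np.float64)
    phase = np.clip((wl - 400.0) / 700.0, 0.0, 1.0)
    return 0.25 + 0.75 * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))


# ---------------------------------------------------------------------------
# scene geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Region:
    """One painted primitive.  ``kind`` is 'ellipse' or 'rectangle'.

    Ellipse params: (center_row, center_col, semi_axis_rows, semi_axis_cols).
    Rectangle params: (row0, col0, row1, col1), half-open on the high edge.
    """

    tissue_class: str
    kind: str
    params: tuple[float, ...]

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        rows, cols = shape
        rr, cc = np.mgrid[0:rows, 0:cols]
        if self.kind == "ellipse":
            cr, cc0, ar, ac = self.params
            return ((rr - cr) / ar) ** 2 + ((cc - cc0) / ac) ** 2 <= 1.0
        if self.kind == "rectangle":
            r0, c0, r1, c1 = (int(p) for p in self.params)
            out = np.zeros(shape, dtype=bool)
            out[max(r0, 0) : r1, max(c0, 0) : c1] = True
            return out
        raise ValueError(f"unknown region kind {self.kind!r}")


@dataclass(frozen=True)
class SceneLayout:
    """Tissue regions painted in order onto a background class."""

    shape: tuple[int, int]
    regions: tuple[Region, ...]
    background_class: str

    def class_names(self) -> list[str]:
        names = [self.background_class]
        for region in self.regions:
            if region.tissue_class not in names:
                names.append(region.tissue_class)
        return names

    def rasterize(self) -> LabelMask:
        names = self.class_names()
        labels = np.zeros(self.shape, dtype=np.int64)
        for region in self.regions:  # later regions occlude earlier ones
            labels[region.rasterize(self.shape)] = names.index(region.tissue_class)
        return LabelMask(labels=labels, class_names=names)


def default_scene(
    shape: tuple[int, int] = (80, 80),
    tumor_center: tuple[float, float] = (48.0, 34.0),
    tumor_axes: tuple[float, float] = (16.0, 19.0),
    include_rsf: bool = True,
) -> SceneLayout:
    """Kidney-specimen mock-up: fat rim, NRP interior, RSF pocket, tumor ellipse.

    With the defaults the tumor covers ~15% of pixels and every class holds
    at least 10 non-overlapping 3×3 ROIs.
    """
    rows, cols = shape
    regions = [Region("NRP", "rectangle", (6, 6, rows - 6, cols - 6))]
    if include_rsf:
        regions.append(Region("RSF", "ellipse", (20.0, 58.0, 8.0, 10.0)))
    regions.append(
        Region("tumor", "ellipse", (*tumor_center, *tumor_axes))
    )
    return SceneLayout(shape=shape, regions=tuple(regions), background_class="fat")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _glare_mask(shape: tuple[int, int], fraction: float, rng) -> np.ndarray:
    """Spatially clustered glare: random disks grown until the pixel budget."""
    mask = np.zeros(shape, dtype=bool)
    target = int(round(fraction * mask.size))
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    guard = 0
    while mask.sum() < target and guard < 10_000:
        cr, ccol = rng.integers(0, rows), rng.integers(0, cols)
        radius = rng.integers(1, 4)
        mask |= (rr - cr) ** 2 + (cc - ccol) ** 2 <= radius**2
        guard += 1
    # trim overshoot deterministically so the budget is approximate from above
    return mask


def render_phantom(
    layout: SceneLayout,
    recipes: dict[str, TissueRecipe],
    wavelengths_nm: np.ndarray = DEFAULT_WAVELENGTHS_NM,
    noise_sd: float = 0.01,
    glare_fraction: float = 0.0,
    seed: int = 0,
    library: Sequence[AbsorptionComponent] | None = None,
    field_of_view_id: str = "phantom",
    standard_reflectance: float = 0.99,
    glare_level: float = 0.98,
) -> tuple[Hypercube, LabelMask, Hypercube]:
    """Render a reflectance phantom, its label mask, and a reference cube.

    Per pixel: absorbance from the pixel's class recipe with per-component
    lognormal weight jitter (CV = ``recipe.weight_cv``), inverted to
    reflectance, multiplied by the instrument response, degraded with
    zero-mean Gaussian noise (truncated at 0) and clustered glare pixels
    set to ``glare_level``.  The reference cube is the same response
    applied to a flat ``standard_reflectance`` reflector.
    """
    if not 0.0 <= glare_fraction <= 1.0:
        raise ValueError("glare_fraction must be in [0, 1]")
    wl = np.asarray(wavelengths_nm, dtype=np.float64)
    mask = layout.rasterize()
    for name in mask.class_names:
        if name not in recipes:
            raise KeyError(f"no recipe for layout class {name!r}")

    rng = np.random.default_rng(seed)
    lib = list(library or default_component_library())
    lib_by_name = {c.name: c for c in lib}
    rows, cols = layout.shape
    absorbance = np.zeros((rows, cols, wl.size))

    for idx, name in enumerate(mask.class_names):
        sel = mask.labels == idx
        npix = int(sel.sum())
        if npix == 0:
            continue
        recipe = recipes[name]
        comp_names = [n for n, w in recipe.component_weights.items() if w > 0]
        for n in comp_names:
            if n not in lib_by_name:
                raise KeyError(f"unknown absorption component {n!r}")
        basis = np.stack([lib_by_name[n].evaluate(wl) for n in comp_names])
        base_w = np.array([recipe.component_weights[n] for n in comp_names])
        if any(w < 0 for w in recipe.component_weights.values()):
            raise ValueError("negative component weight")
        if recipe.weight_cv > 0:
            sigma = np.sqrt(np.log1p(recipe.weight_cv**2))
            jitter = rng.lognormal(
                mean=-0.5 * sigma**2, sigma=sigma, size=(npix, len(comp_names))
            )
        else:
            jitter = np.ones((npix, len(comp_names)))
        weights = base_w[None, :] * jitter
        absorbance[sel] = recipe.baseline_absorbance + weights @ basis

    response = instrument_response(wl)
    raw = np.power(10.0, -absorbance) * response[None, None, :]
    if noise_sd > 0:
        raw = raw + rng.normal(0.0, noise_sd, size=raw.shape)
        raw = np.maximum(raw, 0.0)
    if glare_fraction > 0:
        glare = _glare_mask(layout.shape, glare_fraction, rng)
        raw[glare] = glare_level

    cube = Hypercube(
        values=raw,
        wavelengths_nm=wl.copy(),
        mode=REFLECTANCE,
        field_of_view_id=field_of_view_id,
    )
    reference = Hypercube(
        values=np.broadcast_to(
            standard_reflectance * response, raw.shape
        ).copy(),
        wavelengths_nm=wl.copy(),
        mode=REFLECTANCE,
        field_of_view_id=f"{field_of_view_id}-reference",
    )
    return cube, mask, reference


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


@dataclass
class PhantomFOV:
    """One rendered acquisition of one phantom specimen."""

    specimen_id: str
    field_of_view_id: str
    cube: Hypercube
    mask: LabelMask
    reference: Hypercube
    layout: SceneLayout


def default_cohort(
    n_specimens: int = 6,
    n_fovs: int = 2,
    noise_sd: float = 0.01,
    glare_fraction: float = 0.01,
    seed: int = 0,
    shape: tuple[int, int] = (80, 80),
    recipes: dict[str, TissueRecipe] | None = None,
    wavelengths_nm: np.ndarray = DEFAULT_WAVELENGTHS_NM,
) -> list[PhantomFOV]:
    """Render the default study cohort: ``n_specimens`` × ``n_fovs`` phantoms.

    Each specimen gets a slightly different tumor geometry (seeded jitter of
    the ellipse center and axes); every FOV gets independent noise/glare.
    """
    recipes = recipes or default_tissue_recipes()
    rng = np.random.default_rng(seed)
    cohort: list[PhantomFOV] = []
    for s in range(n_specimens):
        center = (
            48.0 + float(rng.uniform(-4, 4)),
            34.0 + float(rng.uniform(-4, 4)),
        )
        axes = (
            16.0 + float(rng.uniform(-2, 2)),
            19.0 + float(rng.uniform(-2, 2)),
        )
        layout = default_scene(shape=shape, tumor_center=center, tumor_axes=axes)
        for f in range(n_fovs):
            fov_id = f"S{s:02d}F{f}"
            fov_seed = int(rng.integers(0, 2**31 - 1))
            cube, mask, reference = render_phantom(
                layout,
                recipes,
                wavelengths_nm=wavelengths_nm,
                noise_sd=noise_sd,
                glare_fraction=glare_fraction,
                seed=fov_seed,
                field_of_view_id=fov_id,
            )
            cohort.append(
                PhantomFOV(
                    specimen_id=f"S{s:02d}",
                    field_of_view_id=fov_id,
                    cube=cube,
                    mask=mask,
                    reference=reference,
                    layout=layout,
                )
            )
    return cohort
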