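"""Shared fixtures: phantoms, spectra and cohorts built at test time."""

from dataclasses import replace

import numpy as np
import pytest

from mcidetect.hypercube import (
    SpectrumSet,
    concat_spectra,
    correct_instrument_response,
    crop_spectral_range,
    extract_roi_spectra,
    reflectance_to_absorbance,
    vector_normalize,
)
from mcidetect.synthetic import (
    DEFAULT_WAVELENGTHS_NM,
    default_cohort,
    default_scene,
    default_tissue_recipes,
    render_phantom,
)


@pytest.fixture(scope="session")
def wavelengths():
    return DEFAULT_WAVELENGTHS_NM.copy()


@pytest.fixture(scope="session")
def clean_recipes():
    """Default kidney recipes with per-pixel weight jitter disabled."""
    return {k: replace(v, weight_cv=0.0) for k, v in default_tissue_recipes().items()}


@pytest.fixture(scope="session")
def noise_free_phantom(clean_recipes):
    """(cube, mask, reference) with no noise, no glare, no jitter."""
    layout = default_scene()
    return render_phantom(
        layout, clean_recipes, noise_sd=0.0, glare_fraction=0.0, seed=11
    )


@pytest.fixture(scope="session")
def study_cohort():
    """The default seeded phantom cohort at the study noise level."""
    return default_cohort(noise_sd=0.01, glare_fraction=0.01, seed=0)


def preprocess_cohort(cohort, lo=520.0, hi=1050.0, roi_seed=1000):
    """Correct, convert, crop and extract normalized ROI signatures."""
    corrected, absorbance, sets = [], [], []
    for i, fov in enumerate(cohort):
        corr = correct_instrument_response(fov.cube, fov.reference)
        crop = crop_spectral_range(corr, lo, hi)
        ab = reflectance_to_absorbance(crop)
        corrected.append(crop)
        absorbance.append(ab)
        sets.append(extract_roi_spectra(ab, fov.mask, seed=roi_seed + i))
    return corrected, absorbance, vector_normalize(concat_spectra(sets))


@pytest.fixture(scope="session")
def study_spectra(study_cohort):
    """Normalized signature spectra from the default cohort."""
    _, _, spectra = preprocess_cohort(study_cohort)
    return spectra


@pytest.fixture()
def toy_spectra():
    """Two well-separated classes, two FOVs each, on a tiny axis."""
    rng = np.random.default_rng(42)
    wl = np.arange(500.0, 600.0, 10.0)
    base = 1.0 + 0.1 * np.sin(wl / 30.0)
    bump = np.exp(-((wl - 550.0) ** 2) / 200.0)
    values, classes, fovs = [], [], []
    for fov in ("F0", "F1"):
        for _ in range(10):
            values.append(base + 0.5 * bump + rng.normal(0, 0.01, wl.size))
            classes.append("tumor")
            fovs.append(fov)
            values.append(base + rng.normal(0, 0.01, wl.size))
            classes.append("other")
            fovs.append(fov)
    spectra = SpectrumSet(
        wavelengths_nm=wl,
        values=np.vstack(values),
        tissue_class=classes,
        field_of_view_id=fovs,
        roi_id=[f"r{i}" for i in range(len(classes))],
    )
    return vector_normalize(spectra)
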