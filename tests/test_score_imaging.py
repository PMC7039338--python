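"""Score-image generation, wavelength-pair selection, SNR/AUROC evaluation."""

import numpy as np
import pytest

from mcidetect.chemometrics import compute_roc, fit_plsda
from mcidetect.hypercube import (
    Hypercube,
    LabelMask,
    correct_instrument_response,
    crop_spectral_range,
    reflectance_to_absorbance,
)
from mcidetect.score_imaging import (
    ScoreImage,
    WavelengthPair,
    evaluate_score_image,
    plsda_score_image,
    ratiometric_score_image,
    select_wavelength_pair,
)
from mcidetect.synthetic import (
    AbsorptionComponent,
    Region,
    SceneLayout,
    TissueRecipe,
    render_phantom,
)

from conftest import preprocess_cohort


@pytest.fixture(scope="module")
def two_component_phantom():
    """Target absorbs only near 450 nm, background only near 500 nm."""
    wl = np.arange(400.0, 550.0, 5.0)  # 30 bands
    lib = [
        AbsorptionComponent("A", ((450.0, 5.0, 1.0),)),
        AbsorptionComponent("B", ((500.0, 5.0, 1.0),)),
    ]
    recipes = {
        "target": TissueRecipe("target", {"A": 0.8}, baseline_absorbance=0.2,
                               weight_cv=0.1),
        "bg": TissueRecipe("bg", {"B": 0.8}, baseline_absorbance=0.2,
                           weight_cv=0.1),
    }
    layout = SceneLayout(
        shape=(40, 40),
        regions=(Region("target", "ellipse", (20.0, 20.0, 8.0, 8.0)),),
        background_class="bg",
    )
    cube, mask, ref = render_phantom(
        layout, recipes, wavelengths_nm=wl, noise_sd=0.05, glare_fraction=0.0,
        seed=7, library=lib,
    )
    return correct_instrument_response(cube, ref), mask, wl


@pytest.fixture(scope="module")
def scored_fov(study_cohort, study_spectra):
    model = fit_plsda(study_spectra, "tumor", 5)
    _, absorbance, _ = preprocess_cohort(study_cohort[:1])
    score = plsda_score_image(absorbance[0], model)
    return score, study_cohort[0].mask


class TestPLSDAScoreImage:
    def test_tumor_region_brighter_than_background(self, scored_fov):
        score, mask = scored_fov
        tumor = score.values[mask.class_mask("tumor")]
        rest = score.values[~mask.class_mask("tumor")]
        assert tumor.mean() > rest.mean()

    def test_scores_are_probabilities(self, scored_fov):
        score, _ = scored_fov
        assert score.values.min() >= 0.0 and score.values.max() <= 1.0

    def test_constant_cube_gives_constant_image(self, study_spectra):
        model = fit_plsda(study_spectra, "tumor", 3)
        wl = model.wavelengths_nm
        cube = Hypercube(np.full((4, 4, wl.size), 0.3), wavelengths_nm=wl,
                         mode="absorbance")
        score = plsda_score_image(cube, model)
        assert np.ptp(score.values) == 0.0

    def test_axis_mismatch_rejected(self, study_spectra):
        model = fit_plsda(study_spectra, "tumor", 3)
        wl = model.wavelengths_nm[:-1]
        cube = Hypercube(np.full((2, 2, wl.size), 0.3), wavelengths_nm=wl,
                         mode="absorbance")
        with pytest.raises(ValueError, match="axis"):
            plsda_score_image(cube, model)


class TestRatiometricScoreImage:
    def test_self_ratio_is_unity(self, two_component_phantom):
        cube, _, wl = two_component_phantom
        # numerator and denominator resolve to the same band contents
        twin = Hypercube(
            np.repeat(cube.values[:, :, :1], 2, axis=2),
            wavelengths_nm=np.array([500.0, 505.0]),
        )
        score = ratiometric_score_image(twin, (500.0, 505.0))
        assert np.allclose(score.values[score.valid_mask()], 1.0)

    def test_illumination_scale_invariance(self, two_component_phantom):
        cube, _, wl = two_component_phantom
        scaled = Hypercube(cube.values * 3.7, wavelengths_nm=wl)
        plain = Hypercube(cube.values.copy(), wavelengths_nm=wl)
        a = ratiometric_score_image(plain, (500.0, 450.0))
        b = ratiometric_score_image(scaled, (500.0, 450.0))
        ok = a.valid_mask() & b.valid_mask()
        assert np.allclose(a.values[ok], b.values[ok], rtol=1e-12)

    def test_off_axis_wavelength_rejected(self, two_component_phantom):
        cube, _, _ = two_component_phantom
        with pytest.raises(ValueError, match="off the wavelength axis"):
            ratiometric_score_image(cube, (600.0, 500.0))  # beyond the axis

    def test_kidney_pair_makes_tumor_bright(self, study_cohort):
        """Water-rich tumor is brightest when ~915 nm is divided by ~1000 nm."""
        fov = study_cohort[0]
        corr = correct_instrument_response(fov.cube, fov.reference)
        score = ratiometric_score_image(corr, (915.0, 1000.0))
        tumor = score.values[fov.mask.class_mask("tumor") & score.valid_mask()]
        rest = score.values[~fov.mask.class_mask("tumor") & score.valid_mask()]
        assert np.median(tumor) > np.median(rest)

    def test_zero_denominator_flagged(self):
        vals = np.ones((2, 2, 2))
        vals[0, 0, 1] = 0.0
        cube = Hypercube(vals, wavelengths_nm=np.array([500.0, 505.0]))
        score = ratiometric_score_image(cube, (500.0, 505.0))
        assert not score.validity[0, 0]
        assert score.validity[1, 1]


class TestWavelengthPairSelection:
    def test_constructed_optimum_recovered_and_matches_oracle(
        self, two_component_phantom
    ):
        corr, mask, wl = two_component_phantom
        pair = select_wavelength_pair(
            [(corr, mask)], target_class="target", scope="single_specimen",
            max_pixels_per_cube=10_000, seed=0,
        )
        # reflectance terms: bright where absorption is low → numerator at the
        # background's absorption band, denominator at the target's
        assert (pair.numerator_nm, pair.denominator_nm) == (500.0, 450.0)

        usable = np.all(corr.values > 1e-8, axis=2) & corr.valid_mask()
        flat = corr.values[usable]
        is_target = mask.class_mask("target")[usable].astype(int)
        best = (-1.0, None)
        for i in range(wl.size):
            for j in range(wl.size):
                if i == j:
                    continue
                auc = compute_roc(flat[:, i] / flat[:, j], is_target).auroc
                if auc > best[0]:
                    best = (auc, (float(wl[i]), float(wl[j])))
        assert best[1] == (pair.numerator_nm, pair.denominator_nm)
        assert pair.contrast_score == pytest.approx(best[0], abs=1e-12)

    def test_consistent_case_over_identical_cubes_degenerates(
        self, two_component_phantom
    ):
        corr, mask, _ = two_component_phantom
        single = select_wavelength_pair(
            [(corr, mask)], "target", scope="single_specimen",
            max_pixels_per_cube=10_000,
        )
        consistent = select_wavelength_pair(
            [(corr, mask), (corr, mask)], "target", scope="consistent_case",
            max_pixels_per_cube=10_000,
        )
        assert (single.numerator_nm, single.denominator_nm) == (
            consistent.numerator_nm, consistent.denominator_nm,
        )

    def test_identical_pair_rejected(self):
        with pytest.raises(ValueError, match="must differ"):
            WavelengthPair(500.0, 500.0)


class TestScoreEvaluation:
    def make_mask(self, labels, names):
        return LabelMask(np.asarray(labels), class_names=names)

    def test_snr_formula_forced_arithmetic(self):
        values = np.array([
            [10.0, 10.0, 1.0, 3.0],
            [10.0, 10.0, 1.0, 3.0],
        ])
        labels = np.array([[1, 1, 0, 0], [1, 1, 0, 0]])
        mask = self.make_mask(labels, ["other", "tumor"])
        score = ScoreImage(values, provenance="ratiometric")
        snr, _ = evaluate_score_image(score, mask, "tumor")
        # target mean 10, background mean 2, population sd 1 → SNR = 8
        assert snr == pytest.approx(8.0)

    def test_truth_as_score_gives_perfect_auroc(self):
        labels = np.zeros((6, 6), dtype=int)
        labels[2:4, 2:4] = 1
        mask = self.make_mask(labels, ["other", "tumor"])
        score = ScoreImage(labels.astype(float), provenance="ratiometric")
        snr, auroc = evaluate_score_image(score, mask, "tumor")
        assert auroc == 1.0
        assert snr == np.inf  # constant background, separated means

    def test_random_score_near_chance(self):
        rng = np.random.default_rng(123)
        labels = np.zeros((40, 40), dtype=int)
        labels[:, :20] = 1
        mask = self.make_mask(labels, ["other", "tumor"])
        score = ScoreImage(rng.uniform(size=(40, 40)), provenance="ratiometric")
        _, auroc = evaluate_score_image(score, mask, "tumor")
        assert auroc == pytest.approx(0.5, abs=0.05)

    def test_shift_invariance_and_scale_linearity(self):
        rng = np.random.default_rng(5)
        labels = np.zeros((10, 10), dtype=int)
        labels[:5] = 1
        mask = self.make_mask(labels, ["other", "tumor"])
        vals = rng.uniform(1, 2, size=(10, 10)) + labels
        s0 = evaluate_score_image(ScoreImage(vals, "ratiometric"), mask, "tumor")
        s_shift = evaluate_score_image(
            ScoreImage(vals + 7.0, "ratiometric"), mask, "tumor"
        )
        s_scale = evaluate_score_image(
            ScoreImage(vals * 3.0, "ratiometric"), mask, "tumor"
        )
        assert s_shift.snr == pytest.approx(s0.snr)
        assert s_shift.auroc == pytest.approx(s0.auroc)
        assert s_scale.snr == pytest.approx(s0.snr)  # ratio is scale-free
        assert s_scale.auroc == pytest.approx(s0.auroc)

    def test_degenerate_constant_score_is_error(self):
        # zero background variance AND zero mean difference: SNR is 0/0
        labels = np.array([[1, 0], [1, 0]])
        mask = self.make_mask(labels, ["other", "tumor"])
        score = ScoreImage(np.ones((2, 2)), "ratiometric")
        with pytest.raises(ValueError, match="zero variance"):
            evaluate_score_image(score, mask, "tumor")
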