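"""PLS-DA fitting, cross-validation, ROC, factor selection, dendrogram."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from mcidetect.chemometrics import (
    BINARY,
    ONE_VS_ALL,
    PLSDAModel,
    class_dendrogram,
    compute_roc,
    confusion_matrix,
    cross_validate,
    fit_multiclass_plsda,
    fit_plsda,
    select_n_factors,
)
from mcidetect.hypercube import SpectrumSet, vector_normalize


def pair_counting_auroc(scores, truth):
    """Brute-force Mann–Whitney AUROC over all positive/negative pairs."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, int)
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (pos.size * neg.size)


def make_spectra(values, classes, fovs=None, normalized=True):
    values = np.asarray(values, float)
    wl = 400.0 + 5.0 * np.arange(values.shape[1])
    fovs = fovs or ["F0"] * len(classes)
    s = SpectrumSet(wl, values, list(classes), list(fovs),
                    [f"r{i}" for i in range(len(classes))])
    return vector_normalize(s) if normalized else s


class TestBinaryFit:
    def test_separable_classes_one_factor_perfect_training(self, toy_spectra):
        model = fit_plsda(toy_spectra, "tumor", n_factors=1)
        preds = model.predict_class(toy_spectra)
        assert preds == [
            "tumor" if c == "tumor" else "not_tumor"
            for c in toy_spectra.tissue_class
        ]

    def test_full_rank_pls_equals_least_squares(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 6))
        y = (X[:, 0] + 0.5 * rng.normal(size=40) > 0).astype(float)
        wl = 400.0 + 5.0 * np.arange(6)
        spectra = SpectrumSet(
            wl, X, ["pos" if t else "neg" for t in y],
            ["F0"] * 40, [f"r{i}" for i in range(40)], normalized=False,
        )
        spectra.normalized = True  # bypass normalization: oracle needs raw X
        model = fit_plsda(spectra, "pos", n_factors=6)
        raw = spectra.values @ model.coefs[0] + model.intercepts[0]
        Xc = np.column_stack([np.ones(40), X])
        beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        ols = Xc @ beta
        assert np.allclose(raw, ols, atol=1e-6)

    def test_kidney_configuration_accepted(self, study_spectra):
        model = fit_plsda(study_spectra, "tumor", n_factors=5)
        assert model.n_factors == 5
        assert model.wavelengths_nm[0] == 520.0
        assert model.wavelengths_nm[-1] == 1050.0
        assert model.wavelengths_nm.size == 107

    def test_single_class_and_excess_factors_rejected(self, toy_spectra):
        only = toy_spectra.subset(
            [i for i, c in enumerate(toy_spectra.tissue_class) if c == "tumor"]
        )
        with pytest.raises(ValueError, match="class"):
            fit_plsda(only, "tumor", 2)
        with pytest.raises(ValueError, match="n_factors"):
            fit_plsda(toy_spectra, "tumor", n_factors=1000)

    def test_probabilities_clipped_to_unit_interval(self, toy_spectra):
        model = fit_plsda(toy_spectra, "tumor", 3)
        p = model.predict_proba(toy_spectra)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_save_load_round_trip(self, tmp_path, toy_spectra):
        model = fit_plsda(toy_spectra, "tumor", 2)
        model.decision_threshold = 0.47
        model.save(tmp_path / "model.npz")
        back = PLSDAModel.load(tmp_path / "model.npz")
        assert back.decision_threshold == 0.47
        assert np.allclose(
            back.predict_proba(toy_spectra), model.predict_proba(toy_spectra)
        )
        assert np.allclose(back.transform(toy_spectra), model.transform(toy_spectra))


class TestMulticlassFit:
    def test_well_separated_four_class_phantom_zero_misclassification(self):
        """Four tissue classes, each dominated by a different chromophore."""
        from mcidetect.synthetic import TissueRecipe, synthesize_signature

        wl = np.arange(520.0, 1051.0, 5.0)
        rng = np.random.default_rng(0)
        recipes = {
            "tumor": TissueRecipe("tumor", {"water": 0.6}, 0.2),
            "NRP": TissueRecipe("NRP", {"oxyhemoglobin": 0.6}, 0.2),
            "fat": TissueRecipe("fat", {"lipid": 0.6}, 0.2),
            "RSF": TissueRecipe("RSF", {"deoxyhemoglobin": 0.6}, 0.2),
        }
        values, classes, fovs = [], [], []
        for name, recipe in recipes.items():
            sig = synthesize_signature(recipe, wl)
            for fov in ("F0", "F1"):
                for _ in range(10):
                    values.append(sig + rng.normal(0, 0.005, wl.size))
                    classes.append(name)
                    fovs.append(fov)
        spectra = make_spectra(values, classes, fovs)
        model = fit_multiclass_plsda(spectra, n_factors=7)
        assert len(model.class_labels) == 4  # one classifier per tissue type
        preds = model.predict_class(spectra)
        cm = confusion_matrix(preds, spectra.tissue_class, model.class_labels)
        assert all(rate == 0.0 for rate in cm.misclassification_rate.values())

    def test_two_class_one_vs_all_matches_binary_ranking(self, toy_spectra):
        binary = fit_plsda(toy_spectra, "tumor", 2)
        ova = fit_multiclass_plsda(toy_spectra, 2)
        b_scores = binary.predict_proba(toy_spectra)
        o_scores = ova.predict_proba(toy_spectra)[:, ova.class_labels.index("tumor")]
        assert np.array_equal(np.argsort(b_scores), np.argsort(o_scores))


class TestCrossValidation:
    def test_every_spectrum_scored_exactly_once(self, toy_spectra):
        cv = cross_validate(toy_spectra, mode=BINARY, positive_class="tumor",
                            n_factors=2)
        assert cv.scored.all()
        assert len(cv.truth) == len(toy_spectra)

    def test_fold_count_is_classes_times_fovs(self, toy_spectra):
        groups = set(toy_spectra.groups())
        assert len(groups) == 4  # 2 classes × 2 FOVs

    def test_separable_cohort_perfect_cv_accuracy(self, toy_spectra):
        cv = cross_validate(toy_spectra, mode=ONE_VS_ALL, n_factors=2)
        assert cv.predicted_classes() == cv.truth

    def test_leave_one_tissue_out_skips_degenerate_folds(self, toy_spectra):
        cv = cross_validate(
            toy_spectra, scheme="leave_one_tissue_out", mode=BINARY,
            positive_class="tumor", n_factors=2,
        )
        # holding out either tissue leaves a single-class training split
        assert cv.skipped_folds == ["other", "tumor"]
        assert len(cv.truth) == 0

    def test_no_leakage_training_never_sees_held_out_group(self, toy_spectra):
        """Scores differ from training-set scores: fold models are refit."""
        cv = cross_validate(toy_spectra, mode=BINARY, positive_class="tumor",
                            n_factors=2)
        full_model = fit_plsda(toy_spectra, "tumor", 2)
        full_scores = full_model.predict_proba(toy_spectra)
        assert not np.allclose(cv.scores, full_scores)


class TestROC:
    def test_perfect_separation(self):
        roc = compute_roc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert roc.auroc == 1.0
        assert roc.sensitivity_at_optimum == 1.0
        assert roc.specificity_at_optimum == 1.0
        assert roc.distance_from_ideal() == 0.0

    def test_constant_scores_are_chance(self):
        roc = compute_roc([0.5] * 10, [1, 0] * 5)
        assert roc.auroc == pytest.approx(0.5)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_roc([0.1, 0.2], [1, 1])

    def test_sensitivity_monotone_as_threshold_decreases(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=50)
        truth = rng.integers(0, 2, 50)
        roc = compute_roc(scores, truth)
        assert np.all(np.diff(roc.sensitivity) >= 0)
        assert np.all(np.diff(roc.thresholds) < 0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(4, 50))
    def test_auroc_equals_pair_counting_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.uniform(size=n), 2)  # induce ties
        truth = np.zeros(n, dtype=int)
        truth[: max(1, n // 3)] = 1
        rng.shuffle(truth)
        roc = compute_roc(scores, truth)
        assert roc.auroc == pytest.approx(pair_counting_auroc(scores, truth), abs=1e-12)
        assert roc.auroc == pytest.approx(roc_auc_score(truth, scores), abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_auroc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        truth = rng.integers(0, 2, 30)
        if truth.sum() in (0, truth.size):
            truth[0] = 1 - truth[0]
        a = compute_roc(scores, truth).auroc
        b = compute_roc(np.exp(scores) + 3.0, truth).auroc
        assert a == pytest.approx(b, abs=1e-12)


class TestFactorSelection:
    def test_low_rank_classes_need_few_factors(self):
        rng = np.random.default_rng(9)
        wl_n = 20
        d1, d2 = rng.normal(size=wl_n), rng.normal(size=wl_n)
        base = 5.0 + rng.normal(size=wl_n) * 0.1
        values, classes, fovs = [], [], []
        for fov in ("F0", "F1", "F2"):
            for _ in range(8):
                values.append(base + 1.0 * d1 + rng.normal(0, 0.02, wl_n))
                classes.append("tumor")
                fovs.append(fov)
                values.append(base + 1.0 * d2 + rng.normal(0, 0.02, wl_n))
                classes.append("other")
                fovs.append(fov)
        spectra = make_spectra(values, classes, fovs)
        curve = select_n_factors(spectra, "tumor", max_factors=6)
        assert curve.chosen_n_factors <= 3
        assert len(curve.n_factors) == 6
        # distance curve is flat (near its minimum) beyond the true rank
        assert np.all(curve.distance_from_ideal[2:] <= curve.distance_from_ideal.min()
                      + 0.02 + 1e-12)

    def test_max_factors_lower_bound(self, toy_spectra):
        with pytest.raises(ValueError, match="max_factors"):
            select_n_factors(toy_spectra, "tumor", max_factors=1)


class TestConfusionMatrix:
    def test_perfect_predictions(self):
        cm = confusion_matrix(["a", "b", "a"], ["a", "b", "a"], ["a", "b"])
        assert np.array_equal(cm.counts, [[2, 0], [0, 1]])
        assert cm.misclassification_rate == {"a": 0.0, "b": 0.0}

    def test_partial_misclassification_rates(self):
        truth = ["A"] * 10
        pred = ["A"] * 7 + ["B"] * 3
        cm = confusion_matrix(pred, truth, ["A", "B"])
        assert cm.percent[0, 0] == pytest.approx(70.0)
        assert cm.percent[0, 1] == pytest.approx(30.0)
        assert cm.misclassification_rate["A"] == pytest.approx(30.0)

    def test_rows_sum_to_hundred(self):
        rng = np.random.default_rng(2)
        labels = ["x", "y", "z"]
        truth = rng.choice(labels, 60).tolist()
        pred = rng.choice(labels, 60).tolist()
        cm = confusion_matrix(pred, truth, labels)
        sums = cm.percent.sum(axis=1)
        assert np.allclose(sums[np.array([truth.count(c) > 0 for c in labels])], 100.0)

    def test_unknown_label_is_error(self):
        with pytest.raises(ValueError, match="not in class_labels"):
            confusion_matrix(["a"], ["q"], ["a", "b"])


class TestDendrogram:
    def test_two_classes_single_merge_at_centroid_distance(self, toy_spectra):
        model = fit_multiclass_plsda(toy_spectra, 2)
        tree = class_dendrogram(model, toy_spectra)
        assert tree.linkage.shape == (1, 4)
        latent = model.transform(toy_spectra)
        cls = np.array(toy_spectra.tissue_class)
        c0 = latent[cls == tree.class_labels[0]].mean(axis=0)
        c1 = latent[cls == tree.class_labels[1]].mean(axis=0)
        assert tree.linkage[0, 2] == pytest.approx(np.linalg.norm(c0 - c1))

    def test_fat_and_rsf_merge_first(self, study_spectra):
        """The two lipid-dominated tissues are the most similar classes."""
        model = fit_multiclass_plsda(study_spectra, 7)
        tree = class_dendrogram(model, study_spectra)
        first_a, first_b, _ = tree.merge_order()[0]
        assert first_a | first_b == {"fat", "RSF"}

    def test_k_minus_one_merges(self, study_spectra):
        model = fit_multiclass_plsda(study_spectra, 5)
        tree = class_dendrogram(model, study_spectra)
        assert tree.linkage.shape[0] == len(tree.class_labels) - 1
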