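"""PLS-DA tissue discrimination and its evaluation machinery.

Partial least squares discriminant analysis (PLS-DA) regresses a {0, 1}
class response on signature spectra using a small number of latent factors
and thresholds the continuous prediction to classify.  Binary models take
tumor as the positive class and pool every other tissue into the negative
class; multiclass discrimination uses a one-vs-all bank of k binary
models, assigning each sample to the class with the highest score.

The module also provides grouped cross-validation
(leave-one-field-of-view-out and leave-one-tissue-out), ROC analysis with
Youden-optimal thresholding, a cross-validated factor-selection curve
(AUROC / distance-from-ideal-sensor vs number of factors), row-normalized
confusion matrices, and an average-linkage dendrogram of class centroids
in the model's latent-score space.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from sklearn.cross_decomposition import PLSRegression

from .hypercube import SpectrumSet

logger = logging.getLogger(__name__)

BINARY = "binary"
ONE_VS_ALL = "one_vs_all"


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------


def _fit_single(X: np.ndarray, y: np.ndarray, n_factors: int):
    """Fit one PLS regression of a {0,1} response; return its linear form."""
    reg = PLSRegression(n_components=n_factors, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # y residual may become constant
        reg.fit(X, y.astype(np.float64))
    # fold the centering/scaling into an explicit affine form on raw spectra
    coef = reg.coef_.reshape(-1) / reg._x_std
    intercept = float(np.ravel(reg.intercept_)[0] - reg._x_mean @ coef)
    return coef, intercept, reg.x_rotations_.copy(), reg._x_mean.copy()


@dataclass
class PLSDAModel:
    """Fitted latent-variable discriminant model (binary or one-vs-all).

    Each per-class classifier is stored as its equivalent linear form
    (coefficients + intercept) together with the latent rotation so new
    spectra can be both scored and projected into latent space.  Scores
    are clipped to [0, 1] and interpreted as class probabilities.
    """

    class_labels: list[str]
    mode: str
    n_factors: int
    wavelengths_nm: np.ndarray
    coefs: np.ndarray  # (k, n_features)
    intercepts: np.ndarray  # (k,)
    rotations: np.ndarray  # (k, n_features, n_factors)
    x_means: np.ndarray  # (k, n_features)
    decision_threshold: float = 0.5

    @property
    def positive_class(self) -> str:
        if self.mode != BINARY:
            raise ValueError("positive_class is defined for binary models only")
        return self.class_labels[0]

    def _check_axis(self, wavelengths_nm: np.ndarray) -> None:
        if not np.array_equal(wavelengths_nm, self.wavelengths_nm):
            raise ValueError("prediction wavelength axis differs from training axis")

    def _matrix(self, spectra) -> np.ndarray:
        if isinstance(spectra, SpectrumSet):
            self._check_axis(spectra.wavelengths_nm)
            return spectra.values
        return np.atleast_2d(np.asarray(spectra, dtype=np.float64))

    def predict_proba(self, spectra) -> np.ndarray:
        """Clipped-to-[0,1] scores: shape (n,) binary, (n, k) one-vs-all."""
        X = self._matrix(spectra)
        raw = X @ self.coefs.T + self.intercepts[None, :]
        raw = np.clip(raw, 0.0, 1.0)
        return raw[:, 0] if self.mode == BINARY else raw

    def predict_class(self, spectra) -> list[str]:
        scores = self.predict_proba(spectra)
        if self.mode == BINARY:
            other = f"not_{self.positive_class}"
            return [
                self.positive_class if s >= self.decision_threshold else other
                for s in scores
            ]
        return [self.class_labels[i] for i in np.argmax(scores, axis=1)]

    def transform(self, spectra) -> np.ndarray:
        """Latent scores, concatenated over the per-class models: (n, k·f)."""
        X = self._matrix(spectra)
        parts = [
            (X - self.x_means[i][None, :]) @ self.rotations[i]
            for i in range(len(self.class_labels))
        ]
        return np.hstack(parts)

    # -- serialization: JSON header + arrays in one .npz archive ------------

    def save(self, path) -> None:
        header = json.dumps(
            {
                "class_labels": self.class_labels,
                "mode": self.mode,
                "n_factors": self.n_factors,
                "decision_threshold": self.decision_threshold,
            }
        )
        np.savez(
            path,
            header=np.frombuffer(header.encode(), dtype=np.uint8),
            wavelengths_nm=self.wavelengths_nm,
            coefs=self.coefs,
            intercepts=self.intercepts,
            rotations=self.rotations,
            x_means=self.x_means,
        )

    @classmethod
    def load(cls, path) -> "PLSDAModel":
        with np.load(path) as archive:
            header = json.loads(archive["header"].tobytes().decode())
            return cls(
                class_labels=header["class_labels"],
                mode=header["mode"],
                n_factors=int(header["n_factors"]),
                decision_threshold=float(header["decision_threshold"]),
                wavelengths_nm=archive["wavelengths_nm"],
                coefs=archive["coefs"],
                intercepts=archive["intercepts"],
                rotations=archive["rotations"],
                x_means=archive["x_means"],
            )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _validate_factors(n_factors: int, n_samples: int, n_features: int) -> None:
    limit = min(n_samples - 1, n_features)
    if not 1 <= n_factors <= limit:
        raise ValueError(
            f"n_factors must be in [1, {limit}] for {n_samples} samples × "
            f"{n_features} features; got {n_factors}"
        )


def fit_plsda(
    spectra: SpectrumSet, positive_class: str, n_factors: int
) -> PLSDAModel:
    """Fit a binary tumor-vs-rest (positive-vs-all-other) PLS-DA model.

    Spectra must be vector-normalized and share one wavelength axis; the
    decision threshold starts at 0.5 until calibrated from an ROC sweep.
    """
    if not spectra.normalized:
        raise ValueError("fit_plsda expects vector-normalized spectra")
    y = np.array([1.0 if c == positive_class else 0.0 for c in spectra.tissue_class])
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both positive and negative classes must be present")
    _validate_factors(n_factors, len(y), spectra.values.shape[1])
    coef, intercept, rotations, x_mean = _fit_single(spectra.values, y, n_factors)
    return PLSDAModel(
        class_labels=[positive_class],
        mode=BINARY,
        n_factors=n_factors,
        wavelengths_nm=spectra.wavelengths_nm.copy(),
        coefs=coef[None, :],
        intercepts=np.array([intercept]),
        rotations=rotations[None, :, :],
        x_means=x_mean[None, :],
    )


def fit_multiclass_plsda(spectra: SpectrumSet, n_factors: int) -> PLSDAModel:
    """Fit a one-vs-all bank of binary PLS-DA models, one per tissue class."""
    if not spectra.normalized:
        raise ValueError("fit_multiclass_plsda expects vector-normalized spectra")
    classes = spectra.classes
    if len(classes) < 2:
        raise ValueError("need at least two tissue classes")
    _validate_factors(n_factors, len(spectra), spectra.values.shape[1])
    coefs, intercepts, rotations, x_means = [], [], [], []
    for name in classes:
        y = np.array([1.0 if c == name else 0.0 for c in spectra.tissue_class])
        coef, intercept, rot, mean = _fit_single(spectra.values, y, n_factors)
        coefs.append(coef)
        intercepts.append(intercept)
        rotations.append(rot)
        x_means.append(mean)
    return PLSDAModel(
        class_labels=classes,
        mode=ONE_VS_ALL,
        n_factors=n_factors,
        wavelengths_nm=spectra.wavelengths_nm.copy(),
        coefs=np.vstack(coefs),
        intercepts=np.array(intercepts),
        rotations=np.stack(rotations),
        x_means=np.vstack(x_means),
    )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

LEAVE_ONE_FOV_OUT = "leave_one_fov_out"
LEAVE_ONE_TISSUE_OUT = "leave_one_tissue_out"


@dataclass
class CrossValidationResult:
    """Out-of-fold scores plus truth for every scored spectrum."""

    scores: np.ndarray  # (n,) binary or (n, k) one-vs-all
    truth: list[str]
    groups: list[str]
    class_labels: list[str]
    mode: str
    scored: np.ndarray  # bool per input spectrum
    skipped_folds: list[str] = field(default_factory=list)

    def binary_truth(self, positive_class: str | None = None) -> np.ndarray:
        positive = positive_class or self.class_labels[0]
        return np.array([1 if t == positive else 0 for t in self.truth])

    def predicted_classes(self) -> list[str]:
        if self.mode != ONE_VS_ALL:
            raise ValueError("predicted_classes applies to one-vs-all CV")
        return [self.class_labels[i] for i in np.argmax(self.scores, axis=1)]


def cross_validate(
    spectra: SpectrumSet,
    scheme: str = LEAVE_ONE_FOV_OUT,
    mode: str = BINARY,
    positive_class: str = "tumor",
    n_factors: int = 5,
) -> CrossValidationResult:
    """Grouped cross-validation with out-of-fold PLS-DA scoring.

    ``leave_one_fov_out`` folds are tissue-class × field-of-view groups
    (all spectra for one tissue type in one FOV are held out together);
    ``leave_one_tissue_out`` folds are whole tissue classes.  A fold whose
    training split loses an entire class of a binary problem is skipped
    with a warning.
    """
    if scheme == LEAVE_ONE_FOV_OUT:
        groups = spectra.groups()
    elif scheme == LEAVE_ONE_TISSUE_OUT:
        groups = list(spectra.tissue_class)
    else:
        raise ValueError(f"unknown cross-validation scheme {scheme!r}")

    groups_arr = np.array(groups)
    n = len(spectra)
    classes = spectra.classes
    k = len(classes)
    scores = np.full(n if mode == BINARY else (n, k), np.nan)
    scored = np.zeros(n, dtype=bool)
    skipped: list[str] = []

    for fold in sorted(set(groups)):
        test = groups_arr == fold
        train_idx = np.flatnonzero(~test)
        train = spectra.subset(train_idx)
        try:
            if mode == BINARY:
                model = fit_plsda(train, positive_class, n_factors)
            else:
                if len(train.classes) < k:
                    raise ValueError("training split lost a class")
                model = fit_multiclass_plsda(train, n_factors)
        except ValueError as exc:
            logger.warning("skipping fold %s: %s", fold, exc)
            skipped.append(fold)
            continue
        fold_scores = model.predict_proba(spectra.subset(np.flatnonzero(test)))
        if mode == ONE_VS_ALL:
            # column order may differ per fold; align to the global class list
            aligned = np.full((fold_scores.shape[0], k), np.nan)
            for j, name in enumerate(model.class_labels):
                aligned[:, classes.index(name)] = fold_scores[:, j]
            fold_scores = aligned
        scores[test] = fold_scores
        scored[test] = True

    keep = np.flatnonzero(scored)
    return CrossValidationResult(
        scores=scores[keep],
        truth=[spectra.tissue_class[i] for i in keep],
        groups=[groups[i] for i in keep],
        class_labels=classes if mode == ONE_VS_ALL else [positive_class],
        mode=mode,
        scored=scored,
        skipped_folds=skipped,
    )


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------


@dataclass
class ROCResult:
    """Threshold sweep: per-threshold sensitivity/specificity, AUROC, optimum."""

    thresholds: np.ndarray  # descending
    sensitivity: np.ndarray
    specificity: np.ndarray
    auroc: float
    optimal_threshold: float
    sensitivity_at_optimum: float
    specificity_at_optimum: float

    def distance_from_ideal(self) -> float:
        """Euclidean distance of the optimum from the ideal (100%/100%) sensor."""
        return float(
            np.hypot(
                1.0 - self.sensitivity_at_optimum, 1.0 - self.specificity_at_optimum
            )
        )


def compute_roc(scores, truth) -> ROCResult:
    """ROC by sweeping a threshold across scores (predict positive at ≥ t).

    AUROC is computed by trapezoidal integration of the (1−specificity,
    sensitivity) curve.  The optimal threshold maximizes Youden's
    J = sensitivity + specificity − 1; ties resolve to the higher
    specificity (and then to the higher threshold).
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth).astype(int)
    if scores.shape != truth.shape or scores.ndim != 1:
        raise ValueError("scores and truth must be equal-length 1-D sequences")
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present in truth")

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_truth = truth[order]
    distinct = np.flatnonzero(np.diff(sorted_scores)) # last index of each tie block
    block_ends = np.r_[distinct, sorted_truth.size - 1]
    tp = np.cumsum(sorted_truth)[block_ends]
    fp = (block_ends + 1) - tp
    thresholds = sorted_scores[block_ends]
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg

    fpr = np.r_[0.0, fp / n_neg]
    tpr = np.r_[0.0, sens]
    auroc = float(np.trapezoid(tpr, fpr))

    youden = sens + spec - 1.0
    best = np.flatnonzero(np.isclose(youden, youden.max()))
    best = best[np.argsort(-spec[best], kind="stable")]
    best_idx = int(best[0])
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auroc=auroc,
        optimal_threshold=float(thresholds[best_idx]),
        sensitivity_at_optimum=float(sens[best_idx]),
        specificity_at_optimum=float(spec[best_idx]),
    )


# ---------------------------------------------------------------------------
# factor selection
# ---------------------------------------------------------------------------


@dataclass
class FactorSelectionCurve:
    """Cross-validated performance per candidate factor count."""

    n_factors: np.ndarray
    auroc: np.ndarray
    one_minus_auroc: np.ndarray
    distance_from_ideal: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    chosen_n_factors: int

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "n_factors": self.n_factors,
                "auroc": self.auroc,
                "one_minus_auroc": self.one_minus_auroc,
                "distance_from_ideal": self.distance_from_ideal,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def select_n_factors(
    spectra: SpectrumSet,
    positive_class: str = "tumor",
    scheme: str = LEAVE_ONE_FOV_OUT,
    max_factors: int = 10,
    tolerance: float = 0.02,
) -> FactorSelectionCurve:
    """Sweep the retained-factor count and pick the elbow automatically.

    For each candidate count the model is rebuilt under cross-validation;
    the curve records AUROC, 1−AUROC, sensitivity/specificity at the
    Youden-optimal threshold and the distance from the ideal sensor
    (100% sensitivity, 100% specificity).  The chosen count is the
    smallest whose distance is within ``tolerance`` of the global minimum
    — an automated surrogate for reading the elbow off the curve.
    """
    if max_factors < 2:
        raise ValueError("max_factors must be at least 2")
    counts = np.arange(1, max_factors + 1)
    aurocs, dists, sens, specs = [], [], [], []
    for nf in counts:
        cv = cross_validate(
            spectra,
            scheme=scheme,
            mode=BINARY,
            positive_class=positive_class,
            n_factors=int(nf),
        )
        roc = compute_roc(cv.scores, cv.binary_truth(positive_class))
        aurocs.append(roc.auroc)
        dists.append(roc.distance_from_ideal())
        sens.append(roc.sensitivity_at_optimum)
        specs.append(roc.specificity_at_optimum)
    dists_arr = np.array(dists)
    chosen = int(counts[np.flatnonzero(dists_arr <= dists_arr.min() + tolerance)[0]])
    return FactorSelectionCurve(
        n_factors=counts,
        auroc=np.array(aurocs),
        one_minus_auroc=1.0 - np.array(aurocs),
        distance_from_ideal=dists_arr,
        sensitivity=np.array(sens),
        specificity=np.array(specs),
        chosen_n_factors=chosen,
    )


# ---------------------------------------------------------------------------
# confusion matrix and class dendrogram
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """Counts (row = truth, column = prediction) with row-normalized percent."""

    class_labels: list[str]
    counts: np.ndarray
    percent: np.ndarray
    misclassification_rate: dict[str, float]  # per class, in percent

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.percent, index=self.class_labels, columns=self.class_labels
        )


def confusion_matrix(predicted, truth, class_labels) -> ConfusionMatrix:
    """Row-normalized confusion matrix plus per-class misclassification rate.

    The misclassification rate of a class is the percentage of its samples
    predicted out-of-class (100 − its diagonal percentage).
    """
    labels = list(class_labels)
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have equal length")
    index = {c: i for i, c in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for p, t in zip(predicted, truth):
        if t not in index or p not in index:
            raise ValueError(f"label {t if t not in index else p!r} not in class_labels")
        counts[index[t], index[p]] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = np.where(row_sums > 0, 100.0 * counts / row_sums, 0.0)
    rates = {
        c: float(100.0 - percent[i, i]) if row_sums[i, 0] else float("nan")
        for i, c in enumerate(labels)
    }
    return ConfusionMatrix(
        class_labels=labels,
        counts=counts,
        percent=percent,
        misclassification_rate=rates,
    )


@dataclass
class ClassDendrogram:
    """Hierarchical class relationships from latent-space centroids."""

    class_labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix, (k-1, 4)

    def merge_order(self) -> list[tuple[frozenset, frozenset, float]]:
        """Merges in order: (member classes A, member classes B, height)."""
        clusters: dict[int, frozenset] = {
            i: frozenset([c]) for i, c in enumerate(self.class_labels)
        }
        merges = []
        nxt = len(self.class_labels)
        for a, b, height, _ in self.linkage:
            left, right = clusters[int(a)], clusters[int(b)]
            merges.append((left, right, float(height)))
            clusters[nxt] = left | right
            nxt += 1
        return merges


def class_dendrogram(model: PLSDAModel, spectra: SpectrumSet) -> ClassDendrogram:
    """Average-linkage dendrogram of class centroids in latent-score space.

    Spectra are projected through the fitted one-vs-all model's latent
    rotations; per-class centroids are clustered agglomeratively with
    average linkage on Euclidean distances.
    """
    if model.mode != ONE_VS_ALL:
        raise ValueError("class_dendrogram requires a fitted one-vs-all model")
    if len(model.class_labels) < 2:
        raise ValueError("need at least two classes")
    latent = model.transform(spectra)
    centroids = []
    for name in model.class_labels:
        sel = [i for i, c in enumerate(spectra.tissue_class) if c == name]
        if not sel:
            raise ValueError(f"no spectra for class {name!r}")
        centroids.append(latent[sel].mean(axis=0))
    linkage = hierarchy.linkage(np.vstack(centroids), method="average", metric="euclidean")
    return ClassDendrogram(class_labels=list(model.class_labels), linkage=linkage)
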