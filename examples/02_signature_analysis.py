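"""Multiclass signature analysis: confusion matrix and class dendrogram.

Preprocesses a small phantom cohort (instrument correction, absorbance,
520-1050 nm crop, ROI signature extraction, vector normalization), runs
one-vs-all PLS-DA with leave-one-FOV-out cross-validation, and prints the
row-normalized confusion matrix and the order in which tissue classes
merge in the latent-space dendrogram.
"""

from mcidetect import (
    class_dendrogram,
    concat_spectra,
    confusion_matrix,
    correct_instrument_response,
    crop_spectral_range,
    cross_validate,
    default_cohort,
    extract_roi_spectra,
    fit_multiclass_plsda,
    reflectance_to_absorbance,
    vector_normalize,
)

cohort = default_cohort(n_specimens=4, n_fovs=2, noise_sd=0.01, seed=0)
sets = []
for i, fov in enumerate(cohort):
    corrected = correct_instrument_response(fov.cube, fov.reference)
    absorbance = reflectance_to_absorbance(
        crop_spectral_range(corrected, 520.0, 1050.0)
    )
    sets.append(extract_roi_spectra(absorbance, fov.mask, seed=i))
spectra = vector_normalize(concat_spectra(sets))
print(f"{len(spectra)} signatures, {spectra.values.shape[1]} wavelengths, "
      f"classes: {spectra.classes}")

cv = cross_validate(spectra, mode="one_vs_all", n_factors=7)
cm = confusion_matrix(cv.predicted_classes(), cv.truth, spectra.classes)
print("\ncross-validated confusion matrix (% of each true class):")
print(cm.to_dataframe().round(1).to_string())
print("\nper-class misclassification rate (%):",
      {k: round(v, 1) for k, v in cm.misclassification_rate.items()})

model = fit_multiclass_plsda(spectra, n_factors=7)
tree = class_dendrogram(model, spectra)
print("\ndendrogram merge order (most similar classes merge first):")
for a, b, height in tree.merge_order():
    print(f"  {sorted(a)} + {sorted(b)}  at height {height:.4f}")
print("\nFat and RSF — both lipid-dominated — merge first and absorb most of "
      "the confusion; tumor separates cleanly.")
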