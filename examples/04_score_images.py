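"""Tumor score images: PLS-DA versus the two-wavelength ratiometric route.

Trains a binary PLS-DA model, scores one phantom per-pixel, selects a
consistent-case ratiometric wavelength pair across three specimens, and
compares both score images by SNR and pixelwise AUROC against the painted
tumor mask.
"""

from mcidetect import (
    concat_spectra,
    correct_instrument_response,
    crop_spectral_range,
    default_cohort,
    evaluate_score_image,
    extract_roi_spectra,
    fit_plsda,
    plsda_score_image,
    ratiometric_score_image,
    reflectance_to_absorbance,
    select_wavelength_pair,
    vector_normalize,
)

cohort = default_cohort(noise_sd=0.01, glare_fraction=0.01, seed=0)
corrected, absorbance, sets = [], [], []
for i, fov in enumerate(cohort):
    corr = correct_instrument_response(fov.cube, fov.reference)
    crop = crop_spectral_range(corr, 520.0, 1050.0)
    corrected.append(corr)
    absorbance.append(reflectance_to_absorbance(crop))
    sets.append(extract_roi_spectra(absorbance[-1], fov.mask, seed=i))
spectra = vector_normalize(concat_spectra(sets))

model = fit_plsda(spectra, "tumor", n_factors=5)

pair = select_wavelength_pair(
    [(corrected[i], cohort[i].mask) for i in range(3)],
    target_class="tumor",
    scope="consistent_case",
    seed=0,
)
print(f"consistent-case pair: {pair.numerator_nm:g} / {pair.denominator_nm:g} nm "
      f"(worst-case AUROC across specimens: {pair.contrast_score:.3f})")
print("numerator = wavelength where tumor absorbs less than background, "
      "denominator = where it absorbs more,\nso tumor pixels come out bright.\n")

print(f"{'FOV':>6} {'PLS-DA SNR':>11} {'PLS-DA AUROC':>13} "
      f"{'ratio SNR':>10} {'ratio AUROC':>12}")
for i, fov in enumerate(cohort[:4]):
    s_pls = plsda_score_image(absorbance[i], model)
    s_ratio = ratiometric_score_image(corrected[i], pair)
    e_pls = evaluate_score_image(s_pls, fov.mask, "tumor")
    e_ratio = evaluate_score_image(s_ratio, fov.mask, "tumor")
    print(f"{fov.field_of_view_id:>6} {e_pls.snr:11.2f} {e_pls.auroc:13.3f} "
          f"{e_ratio.snr:10.2f} {e_ratio.auroc:12.3f}")
print("\nSNR = (mean tumor - mean background) / background s.d.; AUROC is the "
      "pixelwise separability of tumor from background. The two-wavelength "
      "ratio trades a little contrast for real-time acquisition.")
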