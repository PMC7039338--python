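# Methods

This note records the models, parameter choices and numerical conventions
behind `mcidetect`, and what the synthetic phantoms do and do not show
about real tissue data.

## Hypercube model and preprocessing

A hypercube is a `(rows, cols, bands)` array with a strictly increasing
wavelength axis (the standard acquisition is 400–1100 nm in 5-nm steps,
141 bands) and a mode flag (reflectance or absorbance). All images and
masks use (row, col) indexing, 0-based, origin top-left. Wavelength lookup
is nearest-band within half a band step; anything farther off-axis is an
error rather than a silent snap.

**Instrument correction.** Raw cubes are divided element-wise by a cube of
a reflectance standard and multiplied by the standard's known reflectance
(default 0.99). The rescaling makes the output absolute reflectance rather
than reflectance relative to the standard; without it every absorbance
value would carry a constant offset of log₁₀(1/0.99) ≈ 0.0044. Pixels
where the reference falls below ε = 1e-8 at any band are set to a sentinel
and excluded via a validity mask that propagates through later stages.

**Absorbance.** A = log₁₀(1/R), the standard absorbance convention.
Reflectance at or below a configurable floor (default 1e-6) is clamped
before the logarithm and the clamp count is logged — glare-saturated or
noise-truncated pixels otherwise produce infinities.

**Signatures.** ROI extraction places non-overlapping rectangular ROIs
(default 3×3 px, 10 per tissue class per field of view) uniformly at
random (seeded) wholly inside each class's labeled pixels; each signature
is the unweighted mean of its ROI's pixel spectra, then vector-normalized
(unit Euclidean norm). The ROI geometry and placement rule are this
package's choices; ROI averaging suppresses pixel noise by ~3× for the
default shape, which matters when interpreting noise-sweep results below.

## Synthetic phantoms

Tissue absorbance is modeled as an additive Gaussian mixture over five
chromophore peaks — oxygenated hemoglobin (545, 575 nm), deoxygenated
hemoglobin (755 nm), lipid (930 nm), water (965 nm) — on a per-tissue
baseline. Peak widths (13–30 nm sigma) and tissue weights are free
parameters chosen once to reproduce the qualitative phenomenology of
kidney tissue: tumor carries the highest water weight (0.45), normal renal
parenchyma (NRP) the most hemoglobin, and fat and renal sinus fat (RSF)
lipid weights of 0.50/0.46. Fat and RSF are *deliberately* nearly
identical so that downstream analyses reproduce the expected fat–RSF
confusion and their early merge in the class dendrogram; tests that assert
perfect class separation therefore use either the distinct tissues only or
a purpose-built separable recipe set.

Rendering inverts the preprocessing: per pixel, component weights are
jittered lognormally (CV 0.05 by default), A is synthesized, R = 10⁻ᴬ is
multiplied by a smooth instrument response (raised cosine over 400–1100 nm,
0.25–1.0 — any smooth positive curve works, and the round-trip tests prove
the correction removes it exactly), zero-mean Gaussian noise (truncated at
0) is added, and a chosen fraction of pixels is set to near-saturation in
spatially clustered disks to emulate specular glare. The reference cube
applies the same response to a flat 0.99 reflector.

The default study cohort is 6 specimens × 2 fields of view of 80×80 px,
scaled down from a patient-study scale so the whole pipeline runs in tens
of seconds; each specimen's tumor ellipse (~15% of pixels) is jittered in
position and size. Defaults: noise_sd 0.01, glare 1%.

**What the phantoms do not emulate:** photon transport (scattering,
depth-dependent obscuration such as tumor under a fat layer), necrosis and
blood pooling, inter-patient signature variability beyond weight jitter,
and annotation error at tumor borders. Passing tests on phantoms show the
*algorithms* are implemented correctly and are identifiable under the
stated noise model — not that real-tissue performance will match.

## Chemometrics

PLS-DA is latent-variable regression (NIPALS, via scikit-learn's
`PLSRegression`, unscaled) of a {0,1} class response; the continuous
prediction is clipped to [0,1] and read as a class probability. The
clipped-response mapping is a pragmatic convention — these are not
calibrated posteriors. Multiclass discrimination is one-vs-all: k binary
models, prediction by arg-max score. Fitted models are stored as explicit
affine forms (coefficients, intercept, latent rotation) so serialization
(single `.npz` with a JSON header) is exact and independent of library
internals.

Cross-validation groups are tissue-class × field-of-view (each fold holds
out all spectra of one tissue in one FOV), or whole tissues for the
leave-one-tissue-out scheme. A fold whose training split loses an entire
class of a binary problem is skipped with a warning rather than silently
producing degenerate fits.

ROC analysis sweeps a threshold across the unique scores (predict positive
at score ≥ t), integrates AUROC trapezoidally, and takes the optimal
threshold at the maximum of Youden's J = sensitivity + specificity − 1,
resolving ties toward higher specificity and then higher threshold. The
implementation is checked in tests against both a brute-force
pair-counting (Mann–Whitney) oracle and scikit-learn.

Factor selection rebuilds the model under cross-validation for each
candidate factor count and records AUROC, 1−AUROC, sensitivity/specificity
at the optimum, and the distance from the ideal sensor
√((1−sens)² + (1−spec)²). The chosen count is the smallest whose distance
is within a tolerance (default 0.02) of the global minimum — an automated
surrogate for reading the elbow off the curve; the full curve is always
returned for manual override. On low-rank phantoms this picks 1–2 factors;
real tissue needs more (typically 5–8).

The class dendrogram applies average-linkage agglomerative clustering to
class centroids in the concatenated latent-score space of the one-vs-all
model (Euclidean distances). Linkage and space are this package's choices.

## Score imaging

Ratiometric score images divide one *corrected reflectance* frame by
another. Working in reflectance makes "target absorbs less at the
numerator, more at the denominator" render the target bright. Pair
selection is an exhaustive search over all ordered on-axis pairs scored by
mask-based AUROC of target vs background pixels (background = union of all
non-target tissue classes; a class literally named `background` is treated
as non-tissue and excluded). The per-pair AUROC matrix is computed via the
rank-sum identity with midranks, which equals trapezoidal ROC integration
exactly. The consistent-case scope maximizes the *minimum* AUROC across
specimens (ties → higher mean → lower numerator wavelength); pixels are
subsampled (seeded, default 4000/cube) for tractability on full-size axes.

SNR uses the population standard deviation of the background. A constant
background with separated means yields SNR = ±∞ (infinite contrast); the
error case is reserved for the genuinely undefined situation of zero
variance *and* zero mean difference. Note SNR is invariant — not linear —
under multiplying the score image by a positive constant, since numerator
and denominator scale together; both SNR and AUROC are invariant under
adding a constant, and AUROC under any strictly increasing transform.

## Detection

The cascade is deterministic given its configuration:

1. **Clean** — pixels above the 99.5th percentile or flagged invalid are
   replaced by a 5×5 local median; 3×3 median filter; min–max
   normalization to [0,1]; optional CLAHE. Every step is toggleable.
2. **Segment** — Otsu global threshold (fixed-value override available);
   cascade filters drop connected components below 0.5% of the image
   area, touching the border (toggleable), or with solidity < 0.5; a
   morphological Chan–Vese active contour (200-iteration cap, smoothing 1)
   initialized from the filtered mask refines the boundary. The contour's
   phase is normalized to the bright initialization, since the level-set
   sign is otherwise arbitrary. An empty foreground is a flagged result,
   not an error. The area/border/solidity rules concretize an otherwise
   generic "false-positive suppression" step and are this package's
   design choices.
3. **Register & overlay** — rigid (translation + rotation) alignment of
   the score image to the RGB intensity by maximizing mutual information
   over a 32-bin joint histogram: a coarse integer-translation search
   (radius 8 px) followed by bounded Powell refinement. MI is evaluated
   only over the warped overlap region — including padded borders inflates
   MI and creates spurious optima. Optimizer failure falls back to the
   identity transform with a warning. The detection mask is warped
   (nearest-neighbor) and alpha-blended in the chosen color.

RGB renderings take the bands nearest 630/532/465 nm, each min–max
stretched to 8 bits (a constant channel renders mid-gray).

Detection metrics: IOU = |∩|/|∪| with the convention IOU = 1 when both
masks are empty; sensitivity, specificity and accuracy from the pixel
confusion counts, with degenerate denominators (no positive or no negative
truth pixels) defined as 1.0.

## Pipeline and reproducibility

A run is fully described by a YAML-serializable config plus a seed; every
derived seed is computed arithmetically from it (never from Python's
randomized string hashing), so identical config + seed reproduces
byte-identical metric tables. Stage artifacts are written under the run
directory and hashed (SHA-256) into a manifest. The CLI recomputes earlier
stages from the config rather than re-reading artifacts — the simulator is
deterministic and cheap, which keeps every subcommand self-contained.

## Known limitations

- Phantom realism is deliberately limited (see above); absolute metric
  values on phantoms (AUROC ≈ 1, IOU ≈ 0.98) reflect the phantom's
  separability, not expected clinical performance.
- The clipped-response "probability" is uncalibrated; thresholds
  calibrated by ROC are only meaningful within a comparable acquisition.
- Pair selection is exhaustive O(bands²) with pixel subsampling; on very
  large cubes the subsample controls both cost and (seeded) variability.
- Registration assumes same-instrument geometry (rigid, small offsets);
  affine or deformable alignment is out of scope.
- The active contour can leak along weak gradients if the score image is
  poorly normalized; the cleaning step's normalization is assumed.
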