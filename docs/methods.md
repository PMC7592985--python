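# Methods

## Problem and model

The task is voxel-wise binary classification inside the prostate peripheral
zone (PZ): label each PZ voxel cancer (+1) or noncancer (−1) from
co-registered, same-grid noncontrast mp-MRI channels — T2-weighted imaging
(T2WI), high-b-value DWI, the ADC map, and the three diffusion-tensor
eigenvalue volumes — and turn the classifier's decision values into a
calibrated cancer-probability map. The package assumes bias-corrected,
co-registered inputs with eigenvalues already computed; acquisition,
registration, bias-field correction and tensor fitting belong to upstream
tools and are out of scope. Resampling (trilinear for images, nearest for
masks) only moves channels onto the T2WI grid; it never changes pose.

All in-memory volumes use `(slice, row, column)` axes. Every windowed or
differential operator is two-dimensional and acts per axial slice,
matching slice-wise lesion delineation; the sliding window is 9×9 voxels.

## Reference labels

Each lesion is outlined by two raters. Lesions are matched across raters
by spatial overlap; the *cancer* mask is the union of the voxelwise
intersections of matched pairs, single-rater or zero-overlap lesions are
excluded (and reported, with a 0.25 cc volume annotation for sub-threshold
ones), and *noncancer* is the PZ minus cancer. Consensus labels trade
coverage for certainty: cancer labels under-cover the true lesion and the
discordant ring is labeled noncancer, a deliberate source of label noise
that the evaluation inherits.

## Preprocessing

T2WI intensity is arbitrary per patient, so each patient's (3×3
median-filtered) T2WI is divided by the `median + IQR` of a reference
tissue; the reference is the candidate tissue with the lowest
inter-patient coefficient of variation of that summary
(`%interCV = 100 · sample SD / mean`, n−1 denominator). After division the
patient's reference summary is exactly 1, removing any global scale.
Quantiles use linear interpolation between order statistics (numpy
default, "type 7") throughout; the divisor is computed on the filtered
volume. Standardization applies to T2WI only by default — ADC and
eigenvalues are physical quantities in mm²/s — but is configurable per
channel.

## Features (57 per scalar channel + 20 DTI)

* **Gray level (1):** the channel intensity.
* **First-order (15):** mean, 25th/75th percentile, variance, SD, median,
  IQR, mode, min, max, range, skewness, kurtosis, entropy, energy over the
  9×9 window with edge replication. Moments are population moments;
  kurtosis is excess; degenerate values on constant windows are defined as
  0. Entropy (bits) and energy (Σp²) use a 64-bin histogram of the window
  over its own range; mode is the most frequent bin's centre, ties to the
  lowest bin.
* **GLCM (19):** the window is quantized to 32 equal-width levels over its
  own range; a symmetric co-occurrence matrix is accumulated over the four
  unit offsets (0°, 45°, 90°, 135°) at distance 1 and normalized. The 19
  statistics are GLCM variance and SD, contrast, maximum probability,
  energy, entropy, correlation, maximum correlation coefficient, inertia,
  inverse difference, homogeneity (inverse difference moment),
  dissimilarity, cluster shade, sum average/variance/entropy, sum of
  squares, difference variance/entropy. The feature list names both
  "contrast" and "inertia", classically the same quantity; to keep 19
  distinct columns inertia is computed from the raw pair counts and
  contrast from normalized probabilities. Correlation-type statistics are
  0 when a marginal SD vanishes; the maximum correlation coefficient is 0
  when the matrix occupies fewer than two levels.
* **Edge (6):** binary maps from Roberts, Prewitt, Sobel (gradient
  magnitude > 4× its slice mean), Canny (σ=1, hysteresis at the 0.7/0.9
  magnitude quantiles), Laplacian-of-Gaussian (σ=2 zero crossings with
  jump > 0.75× mean |response|) and a zero-cross detector (same rule on
  the plain Laplacian). The classical operator list names Roberts twice;
  zero-cross completes the set of six.
* **Gradient (16):** Sobel, Prewitt and Roberts each give x, y, diagonal
  (`(Gx+Gy)/√2`) and magnitude responses with unnormalized kernels, plus
  central-difference and forward-difference x/y maps.
* **DTI (20):** from sorted non-negative eigenvalues — FA, RA
  (`√(Σ(λᵢ−MD)²/3)/MD`), VR, Westin Cl/Cp/Cs with the trace denominator
  (so Cl+Cp+Cs = 1), AC, mode (`3√6·det(dev)/‖dev‖³`), MD, λ₁–λ₃, RD,
  λ₁−λ₂, λ₁−λ₃, λ₂−λ₃, VD = λ₁λ₂λ₃, and the three surface products.
  Ratio quantities are 0 where the trace is 0. **AC** ("attenuation
  coefficient") has no standard definition in the literature we could
  anchor to; the package uses the axial-to-radial ratio λ₁/RD (0 where
  RD = 0) and exposes the formula as a pluggable argument. `trace = 3·MD`
  is available as an alias, not a 21st feature. Negative input eigenvalues
  are clamped to 0 with a count rather than rejecting the case.

Channel configurations give 57 (T2), 114 (DWI pair), 77 (T2+DTI),
171 (T2+DWI), or 191 (full) feature columns. Rows with any undefined
feature are dropped and counted.

## Selection, classifier, calibration

Features are min–max scaled to [0, 1] with bounds learned on training rows
only (constant columns map to 0; test values are clipped). CFS scores a
subset by `merit = k·r̄_cf / √(k + k(k−1)·r̄_ff)` on absolute correlations
and grows it best-first, stopping after 5 consecutive non-improving
expansions; the search is deterministic given column order. Note that with
absolute-value correlations pure-noise features have r̄ ≈ 0.8/√n, so on
all-noise data the merit legitimately rises for the first ~1/r̄_ff
additions before stalling — merit stays near 0 but the selected set is not
necessarily a singleton.

The classifier is a soft-margin SVM with the Gaussian kernel
`exp(−γ‖x−x′‖²)` and inverse-frequency class weights (noncancer voxels
outnumber cancer voxels several-fold; without weighting specificity
trivially dominates). `C` and `γ` are tuned on `[10⁻⁴, 10³]` in log10
space by a Gaussian-process (Matérn ν=2.5 + white noise) expected-
improvement loop: 8 seeded space-filling evaluations then EI-chosen ones,
30 evaluations total, objective = mean 10-fold cross-validated AUROC with
folds stratified by class and grouped by patient when enough patients are
available. Because CV AUROC differences far below its sampling noise are
meaningless — and on separable data many (C, γ) tie at AUROC ≈ 1 while
differing wildly as operating points — the incumbent ranks candidates by
AUROC quantized at 0.005 with ties resolved by the cross-validated
balanced accuracy of the sign rule. The objective itself remains AUROC.

Platt calibration fits `P(y=1|f) = 1/(1+exp(Af+B))` to the training
decision values by Newton iteration with backtracking on the regularized
negative log-likelihood, using the smoothed targets
`t₊ = (N₊+1)/(N₊+2)`, `t₋ = 1/(N₋+2)`. Binary maps use `f > 0` (the
decision-function sign); the probability map is the calibrated sigmoid,
missing (NaN) outside the PZ.

## Leave-one-patient-out protocol

For each held-out patient the entire chain — normalization bounds, CFS,
Bayesian optimization, the final SVM, Platt parameters — is refit on the
remaining patients only; per-fold records carry the training patient ids
so leakage is auditable. Folds whose training side lacks a class are
skipped with a warning. Training rows are subsampled (seeded,
class-proportional, ≥25 minority rows) to a per-fold cap of 1600 voxels to
keep the 30×10 cross-validated SVM fits tractable; the cap is a config
knob, and at these phantom sizes raising it does not change the ranking
behaviour, only the runtime.

## Phantom cohorts

The generator emulates the structure the pipeline assumes, per patient:
an ellipsoidal-crescent PZ (~2000 voxels on a 64×64×8 grid at
1.5×1.5×4 mm), 1–2 ellipsoidal lesions of 4.5–7 mm in-plane radius
(≈0.3–0.7 cc, consistent with the ≥0.25 cc lesion regime the labeling
rules assume), a stable reference-tissue block outside the PZ, and five
contrast mechanisms: T2WI (background 1000, lesion −450), high-b DWI
(300, +280), ADC (1.6×10⁻³, −0.8×10⁻³ mm²/s), eigenvalues
((2.1, 1.7, 1.3)×10⁻³ background vs (1.25, 0.85, 0.55)×10⁻³ in-lesion,
i.e. lower MD and higher FA). Signal channels get a ±8 % low-order
multiplicative bias field, Gaussian noise (T2 60, DWI 25, ADC 8×10⁻⁵,
eigenvalues 5×10⁻⁵; a Rician option exists), and a per-patient global
scale drawn from [0.7, 1.3]. The scale applies to the signal-intensity
channels (T2WI, high-b DWI) only: ADC and eigenvalues are physical
quantities, and T2-only standardization is what the pipeline can undo.
The second rater is simulated by one random boundary perturbation (shift,
directional dilation or directional erosion, magnitude ≤ radius); the
default radius 1 is fixed by a seeded Monte-Carlo calibration so the mean
inter-rater Dice falls in [0.70, 0.85].

What the phantom does **not** emulate: anatomically realistic shapes,
partial-volume mixing at lesion boundaries, Rician noise floors at low
SNR (by default), scanner- or protocol-dependent texture, and correlated
multi-channel noise. Passing end-to-end tests therefore demonstrates the
pipeline's correctness and leakage-freedom, not clinical performance on
real patients.

## Numerical choices and degenerate inputs

Missing values are IEEE NaN and excluded everywhere. Constant windows
define entropy 0, energy 1, moments 0. GLCM marginal-degenerate
correlation statistics are 0. Zero-trace eigen-triplets give 0 for all
ratio maps. Dice of two empty masks is 1. Platt's Newton loop ridges the
Hessian by 1e−12 and backtracks on the objective. CFS ties break toward
the earlier column; reference-tissue ties toward the earlier candidate.
The hyperparameter bounds are inclusive and enforced on construction.

## Problem sizes used by tests and the acceptance script

End-to-end runs use 6-patient cohorts on the 64×64×8 grid (~2000 labeled
voxels per patient), full 30-evaluation/10-fold optimization per fold, a
1600-voxel training cap per fold, and 20 label permutations (400-voxel
pool) for the null control — sizes chosen so a complete run is minutes,
not hours, on a single CPU, while every stage still operates in its
intended regime.

## Known limitations

* The sixth edge operator and the AC formula are package conventions
  (documented above); results that depend on those two maps are
  convention-sensitive, as are the GLCM level count (32) and first-order
  histogram bins (64).
* Whether binary metrics should use the sign rule or a tuned probability
  threshold is ambiguous in voxel-wise SVM pipelines; the package uses the
  sign rule and reports Platt probabilities separately.
* Consensus labels make the "noncancer" class impure near lesion
  boundaries; Dice against curated labels therefore saturates below 1
  even for a perfect detector.
* The GP optimizer is a simple EI loop; it is seeded and reproducible but
  makes no claim of global optimality within 30 evaluations.
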