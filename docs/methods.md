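# Methods

This note records the model, the conventions that had to be pinned for the
pipeline to be reproducible, and what the synthetic cohorts do and do not
establish.

## ROI handling

Coordinates are (row, col), 0-based, origin top-left. An ROI is a simple
polygon ring of (row, col) vertices stored as JSON; a pixel belongs to the
mask when its center lies inside or on the ring (even-odd rule,
boundary-inclusive, evaluated with shapely's exact predicates). The
*interior* mask is the 3×3 morphological erosion of the mask: every
interior pixel has its full 8-neighborhood inside the annotation, so 3×3
gradient kernels never mix lesion and background intensities. ROIs smaller
than 64 pixels are rejected at load time (co-occurrence statistics are
meaningless below that; clinical lesions are far larger) — the threshold is
a parameter of `load_lesion`. Color inputs are converted with ITU-R BT.601
luma weights rounded half-up, so conversion is bit-exact.

Texture is computed strictly within the polygon mask, not its bounding box;
a bounding-box implementation would include background pixels and change
every feature value.

## GLCM features (48 + 3)

One co-occurrence matrix per (distance d ∈ {1,2,3}, direction θ ∈
{0°,45°,90°,135°}), counting **ordered** in-mask pixel pairs at a single
displacement per configuration (no symmetrization; a symmetric variant is
one flag away in the descriptor stage since it only transposes-and-adds the
counts). The direction-to-offset map is pinned as 0°→(0,+d), 45°→(−d,+d),
90°→(−d,0), 135°→(−d,−d) because 45°/135° sign conventions differ between
libraries.

Gray levels default to 256. Images whose values already lie in
[0, levels) are used as level indices directly; otherwise values are
rebinned by `floor(g · levels / 256)`, which is order-preserving. This
two-case rule keeps full 8-bit inputs exact at the default while letting
small test images specify levels directly.

Descriptors per matrix: contrast, correlation, energy, homogeneity. The
homogeneity kernel is 1/(1+|a−b|) by default with 1/(1+(a−b)²) available —
both appear in the literature and one had to be chosen. Correlation is
defined as 0 when a marginal variance vanishes (constant ROI), keeping all
features finite for the SVM. The three "global gray" features are
first-order ROI statistics — histogram entropy in nats, mean, population
SD. An alternative reading (statistics of a pooled co-occurrence matrix)
exists; first-order statistics were chosen because the quantities named
(entropy, mean, SD) are standard first-order measures, and the choice is
isolated in `global_gray_features` if a user wants the other one.

All entropies in the package use natural logarithms, consistently.

## GGCM features (15)

Gradients: standard 3×3 Sobel kernels, magnitude = √(Gx²+Gy²), evaluated
only on the interior mask. Magnitudes are quantized to 32 levels by
per-lesion max scaling (`floor(m·32/gmax)` clipped to 31; an all-zero field
maps to level 0). Per-lesion normalization — rather than a fixed global
ceiling — removes dependence on absolute echo brightness, which is exactly
the argument for preferring gradient texture on unstandardized ultrasound.
The gray axis stays at full 256 levels.

The classical GGCM descriptor set has no universally fixed list of 15; the
set implemented (in order) is: small-gradient dominance, large-gradient
dominance, gray heterogeneity, gradient heterogeneity, energy, gray
average, gradient average, gray mean square error (SD), gradient mean
square error (SD), correlation (unnormalized covariance), gray entropy,
**gradient entropy**, hybrid entropy, inertia, inverse difference moment.
Gradient entropy is the member of the classical set most often omitted
from shortened lists and is included here to complete the 15; this is the
one deliberate assumption in the feature set and is worth flagging. The
small-gradient dominance uses (j+1)² in the denominator because the
gradient index is 0-based. Every formula is unit-tested against a direct
double-loop oracle at 1e−12 relative tolerance.

## Classification

Linear-kernel soft-margin SVM with C = 1 under leave-one-out
cross-validation (LOOCV): n lesions, n folds, the held-out lesion never
participates in the fold's standardization statistics or fit. Features are
z-scored per fold (zero-SD features pass through centered at unit scale)
— GGCM features span roughly six orders of magnitude, and an unscaled
linear SVM would be dominated by a single feature. Standardization can be
disabled. A decision score of exactly 0 predicts negative. The procedure
is fully deterministic given the feature table.

**LOOCV bias under the null.** With balanced classes and exchangeable
features, LOOCV accuracy (and pooled-score AUC) is *pessimistically*
biased: removing a positive leaves the training fold tilted toward
negatives, so the held-out positive is more often misclassified. At n = 12
(6/6) the null mean accuracy measures ≈ 0.40, not 0.50; the bias shrinks
with n (null AUC ≈ 0.52 ± 0.04 at n = 60). Tests therefore check that null
performance does not exceed chance, rather than that it equals 0.5 exactly.

## Evaluation

Sensitivity, specificity and accuracy come from the pooled LOOCV confusion
matrix; displayed values are rounded half-up to two decimals (decimal-exact,
not banker's rounding), full precision is kept internally. The ROC is built
from the pooled LOOCV decision scores — one curve per feature combination —
and the AUC is the Mann–Whitney statistic (ties ½), identical to the
trapezoidal area. AUC variance, 95% CI and the paired AUC test use DeLong's
structural components (midrank implementation); the paired test's variance
of the AUC difference accounts for the correlation induced by scoring the
same lesions. Degenerate case: zero difference variance with equal AUCs
returns p = 1 (self-comparison); with unequal AUCs it raises.

Classifier-vs-reader accuracy uses Pearson's chi-square on the 2×2
correct/incorrect table, 1 df, **without** Yates continuity correction (the
uncorrected test matches the published significance pattern for these
margins; the correction is available as a flag). All tests are two-sided at
α = 0.05.

Monte-Carlo calibration (in the acceptance tests): the paired test's type-I
error over 2,000 null replicates at n = 60/60 measures 0.050, and the
DeLong single-curve variance agrees with a 10,000-replicate stratified
bootstrap within 2%.

## Synthetic cohorts

A lesion is `base_intensity × speckle`, where speckle is a gamma field with
mean 1 and SD `speckle_scale` (shape k = 1/scale²), Gaussian-smoothed with
a class-specific sigma, rounded and clipped to 0–255, inside a randomized
star-convex polygon ROI. Defaults: 59 positive / 61 negative lesions
(matching the clinical cohort's class balance), 96-px frames, ROI radii
18–30 px, base intensity 60 (hypoechoic), speckle_scale 0.5 (fully
developed speckle), smoothing sigma 2.0 px (positives) vs 1.0 px
(negatives). The class difference enters *only* through the speckle
correlation length, which alters gradient statistics at matched mean
brightness — the regime in which gradient-based features are the natural
discriminator. Every lesion is generated from an independent substream
spawned from the cohort seed, so cohorts are bit-reproducible and
order-independent.

What the generator does **not** emulate: ultrasound wave physics (PSF,
scan-line geometry, attenuation, shadowing), anatomical context, operator
variability, or the label noise of histology-confirmed but heterogeneous
tumor classes. A green pipeline test on synthetic cohorts therefore
establishes internal correctness and directional behavior (the effect-size
dial moves AUC from ≈ 0.5 to 1 as the smoothing gap grows), *not* clinical
performance; published clinical accuracies cannot be reproduced without
the original images.

## Numerical and degenerate-input choices

- GLCM with an ROI too thin for a displacement raises, naming (d, θ).
- Empty interior mask (ROI thinner than 3 px everywhere) raises before any
  GGCM computation.
- 0·ln 0 ≡ 0 in every entropy.
- Chi-square on a table whose margins make the test undefined (all correct
  or all incorrect in both groups) returns (0, 1).
- Feature vectors are validated to be finite and of the exact expected
  length (48 / 51 / 15) at construction.

## Known limitations

- Single still image per lesion; no multi-frame aggregation.
- No hyperparameter tuning, feature selection, or nested CV — by design,
  to keep the protocol identical to the reference reader-study setting.
- The LOOCV ROC pools scores across folds; fold-wise decision thresholds
  are not calibrated to a common scale beyond per-fold standardization.
- DICOM input and interactive annotation are out of scope.
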