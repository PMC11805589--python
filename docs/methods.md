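# Methods

## The measurement model

A VNIR line-scan camera records raw digital numbers DN(x, y, b) in 273
bands (400–998.4 nm, 2.2 nm spacing by default; any strictly increasing
grid in 300–1100 nm is accepted). With a white diffuse standard in the
scene and an optional shutter-closed dark level, relative reflectance is
the flat-field ratio

    R(x, y, b) = (DN(x, y, b) − dark_b) / (W_b − dark_b),

with W_b the mean DN over the white region. Negative values clip to 0;
values above 1.5 clip with a warning (a diffuse leaf reflects ~0.11 in
the visible, so larger values indicate specular glint or a saturated
standard). Calibration is invariant to a common gain on all DNs. Band
lookup is nearest-neighbour (no interpolation), ties toward the lower
wavelength; windowed quantities average all bands whose centers fall in
the closed window. Per-band SD over the white region is exposed as a
simple sensor-noise estimate; no smoothing or derivative preprocessing
is applied anywhere.

## Scene analysis

Leaf pixels are those with NDVI = (R800 − R670)/(R800 + R670) above a
threshold (default 0.4) in the largest connected component; the red/NIR
contrast is robust on black velvet and indifferent to overall
brightness. Since no image metadata records which half of the blade the
foil covered, the dividing line is either supplied as two pixel
endpoints or taken as the principal axis of the leaf mask ("auto"), and
the caller states which signed side was irradiated. Vein and petiole
tissue carries anomalously high CMI, so exclusion uses a CMI threshold —
by default the 98th percentile of CMI over the leaf, which adapts across
species; an absolute threshold is accepted. Per-pixel index maps
evaluate the registered formula on every pixel; note the mean of an
index map over a region and the index of the region's mean spectrum are
different estimators of the same quantity (indices are nonlinear) and
agree only approximately.

## Indices

Index formulas are registered as expression strings over `R<nm>` tokens
and `mean(R<lo>:R<hi>)` windows, so a formula can be corrected or added
without code changes. The registered forms are the canonical published
narrow-band versions (e.g. NDVI = (R800 − R670)/(R800 + R670),
PRI = (R531 − R570)/(R531 + R570), RGRI = mean(R600:R699)/mean(R500:R599),
CAR1 = 1/R510 − 1/R550; the reciprocal-difference CAR forms are used
rather than the ×R770 NIR-multiplier variants). Pure ratio indices
(including PSRI, which is homogeneous of degree zero) are invariant to
spectrum rescaling; EVI, CAR1 and CAR2 are not. Between-half deltas are
reported as darkened − irradiated.

## The wavelength-pair scan

For each ordered band pair in 400–750 nm, ND(λ1, λ2) is computed per
spectrum from raw reflectance (ND is scale-free, so classifier
normalisation does not apply) and correlated with the binary positioning
label by the point-biserial coefficient, computed as Pearson correlation
with 0/1 dummy coding; avoidance is coded 1 so that positive r marks
indices that rise under avoidance. The diagonal and zero-variance cells
hold NaN; the surface is antisymmetric. Candidates are strict local
maxima of positive r within a (2·radius+1)² neighbourhood (radius 2
bands), with both wavelengths inside the 550–670 nm search window and
neither inside the half-open [500, 550) nm exclusion window (550 itself
is admissible). The neighbourhood comparison is restricted to admissible
cells: when the ridge keeps rising beyond the window boundary, the best
within-window cell is still reported — the search is defined within the
window, as in practice an index is chosen inside a pre-declared region.
Ties rank by higher r, then lower λ1. No multiple-testing correction is
applied over the pair grid; the scan is exploratory.

## Classifiers

Features are spectra truncated to 400–750 nm (160 bands on the default
grid) and divided by their Euclidean norm, so classifiers see shape, not
brightness (mean-normalisation is available as an option; which
normalisation real pipelines use varies, and L2 is the standard choice
when scale invariance is the goal). Three families share one interface:

- **SVM** (scikit-learn SVC, C = 1) with linear, polynomial degree 3/4,
  sigmoid or RBF kernels; class predictions use the decision function
  (Platt-scaled probabilities, exposed via `predict_proba`, can
  contradict the margin on small training sets).
- **MLP**: dense 21-10-3, each non-final layer followed by batch
  normalization and ReLU, softmax head.
- **1-D CNN**: four blocks of (same-padded convolution → ReLU →
  max-pool width 5, stride 2) with kernel widths 11/9/7/5 and feature
  maps 8/16/32/64, then dense 64/32/16/3 with BN+ReLU after the first
  three; ~47k parameters at 160 input bands.

The neural families minimise the multinomial negative log-likelihood
with Adam (lr 1e-3, batch 64), implemented in a small self-contained
numpy core. Two conditioning details matter numerically: network inputs
are rescaled by √(n_bands) so activations and BN statistics sit at unit
order (L2-normalised features have per-band magnitude ~1/√n_bands), and
after training the BN running statistics are replaced by full
training-set population estimates from one extra sweep — momentum
averages lag the final weights badly enough to destabilise
evaluation-mode predictions. Training is bit-reproducible from a seed on
a single thread. The default epoch count is 200; the full protocol value
of 2000 is available via `ModelSpec(epochs=2000)`, but the synthetic
classes saturate well before 200.

Splitting is always grouped by leaf (block spectra augment within a
leaf; pooling a leaf's blocks across partitions would leak): a
stratified 25% leaf-level test set, then 10 repetitions of balanced
5-fold cross-validation on the remainder (per class, shuffled leaves are
dealt round-robin into folds). `evaluate` reports 3×3 row-normalised
confusion matrices, with per-cell mean ± SD over repeated trainings when
given a model specification; `model_select` picks the best mean
validation accuracy, ties toward fewer parameters. Cross-species
evaluation refuses overlapping species sets.

## Welch comparisons

Between-half index deltas are compared across irradiance conditions with
the unequal-variances t statistic t = (ā − b̄)/√(s²_a/n_a + s²_b/n_b),
Welch–Satterthwaite degrees of freedom and a two-sided p (scipy's
implementation behind a thin result type). Two identical zero-variance
samples give t = 0, p = 1 by convention. Multi-group summaries report
unadjusted pairwise p-values and carry an explicit
`familywise_corrected=False` flag; heteroscedastic GLS modelling and
Tukey-style multiple comparisons for multi-factor designs are out of
scope.

## The synthetic generator

No imaging data ship with the package, so a calibrated generator is the
test surface. Each species preset is a parametric template: the
dark-adapted base curve is baseline + green Gaussian bump − blue
absorption well + sigmoid red edge rising to the NIR plateau; the
**avoidance effect** is an additive curve built from blue and red
brightening humps over a low pedestal (physically, reduced absorption
brightens the leaf most where chlorophyll absorbs — blue and red — which
creates the green-yellow "saddle" between the humps), windowed by a rise
at ~412 nm and a steep logistic decline centred ~722 nm (the
700–745 nm fluorescence-quenching decline), plus a narrow trough at
684 nm and peak at 695 nm; the **accumulation effect** is a proportional
darkening of the 490–720 nm window, deepest at the green bump. The dark
class has a zero effect curve.

Free template amplitudes were fitted once by numerical search so that,
noiselessly: dark visible (400–700 nm) mean reflectance = 0.110;
accumulation visible mean effect = −0.006 (a free choice — accumulation
affects indices less than avoidance); avoidance − accumulation visible
mean difference = 0.023; dark-minus-avoidance ΔNDVI = 0.05;
|ΔRGRI| = 0.1. The fitted constants are frozen in the presets. Under
these joint constraints RGRI *rises* under avoidance (the red window
600–699 nm brightens relatively more than the green window), so the
magnitude, not the sign, of ΔRGRI is the calibrated quantity. The hump
geometry (blue hump at 455/34 nm, red hump at 632/24 nm) places the
relative-effect maximum near 637 nm and minimum near 552 nm, so the
wavelength-pair scan recovers a top pair near (635, 555) nm. The two
species presets share the avoidance lobe set (differential-curve
patterns are similar across species) but differ in their base curves —
baseline, green-bump centre/width, blue well, NIR plateau (0.40 vs 0.38)
and red-edge position — enough to make cross-species testing
non-trivial; an early, fully independent per-species avoidance fit made
the signature species-specific enough that the CNN failed to transfer,
which real data say it should not.

Leaf-to-leaf variability is hierarchical; per leaf:

- multiplicative brightness factor ~ N(1, 0.05);
- response amplitude ~ N(1, 0.2) scaling the class effect (leaves differ
  in how strongly they respond);
- resting-arrangement coefficient ~ N(0, 0.45) along the accumulation
  effect direction, applied to every class. This is the source of
  genuine dark/accumulation overlap: dark-adapted leaves differ in how
  "accumulated" their chloroplasts rest, so weakly responding
  accumulation leaves and strongly pre-accumulated dark leaves are
  intrinsically confusable, while avoidance (a large, differently shaped
  effect) stays separable — the qualitative structure real confusion
  matrices show;
- two smooth pigment-variation lobes (Gaussians at 470 and 610 nm,
  coefficients ~ N(0, 0.002));
- a smooth Gaussian-process fine-structure term (squared-exponential,
  SD 0.004, length scale 18 nm). Without it, neighbouring-band ND pairs
  have essentially zero within-class variance and the point-biserial
  surface saturates at arbitrary close-band pairs; with it, close pairs
  pay a noise penalty and the scan optimum is governed by the effect
  shape, as in real spectra;
- per-band sensor noise with SD 0.005/block_px per block spectrum (the
  mean over block_px² pixels).

Scene rendering places an elliptical leaf with a one-pixel main vein
(red-boosted reflectance, hence high CMI) on near-black velvet with a
white reference disk, maps reflectance to DN through a smooth lamp
curve with additive sensor noise (SD 8 DN, dark level 60), and returns
ground-truth masks.

What the generator does **not** emulate: specular/BRDF effects,
spatial texture and venation beyond the single main vein, chlorophyll
content gradients across the blade, transmittance, movement kinetics,
and any species differences beyond the template parameters. Passing
tests therefore demonstrate that the pipeline recovers the encoded
statistical structure at realistic noise levels — not performance on
real cubes.

## Problem sizes and numerical choices

Tests and the acceptance script use 30 leaves per group for calibration
quantities, 120 leaf-half mean spectra for the scan (full 160×160 pair
grid), and 60 leaves/class × 10 block spectra (1800 spectra) with a 25%
leaf-level test split for classification; the CNN trains 200 epochs.
These sizes echo a realistic single-study dataset and keep any script
in the minutes range on one CPU. Degenerate inputs fail loudly:
empty masks, single-class labels, zero-norm spectra, non-positive
white-minus-dark, zero-variance ND cells (NaN sentinel), missing test
classes (NaN confusion row with a warning). ENVI round-trips are
bit-exact for integer cubes; wavelengths serialize with full float
precision.
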