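# Methods

## The problem

Given a segmented 3D lesion in a CT-like volume (intensities on the
Hounsfield scale) and a binary label (benign / malignant), the task is to
characterize lesion heterogeneity by second-order texture and to classify the
lesion from it. The package implements a multi-scale co-occurrence descriptor
and an adaptive, group-wise procedure for integrating its sub-descriptors
into a compact, high-AUC feature set, plus a small CNN alternative that
consumes the co-occurrence matrices directly.

## Region of interest, cleansing and quantization

A lesion ROI is a volume/mask pair on the same grid. Voxels below the
cleansing threshold (default −450 HU) are predominantly air from the colonic
lumen and are removed from the mask rather than zero-filled, so they never
contribute co-occurring pairs. Surviving in-mask intensities are quantized to
`n_levels` gray levels (default 32) by equal-width binning between the
post-cleanse in-mask minimum and maximum — the common radiomics default; the
bounds and threshold are recorded in the ROI's provenance. A constant ROI
quantizes to level 0 everywhere instead of erroring, which keeps pipelines
total; all measures are defined for the resulting delta matrix.

## Multi-scale co-occurrence matrices

A voxel's 26 first-ring neighbours give 26 displacement vectors; since the
matrix of `-v` is the transpose of the matrix of `v`, 13 canonical directions
remain (first nonzero component positive, lexicographic order within each
group — a fixed order so descriptor columns are reproducible). They partition
by Euclidean sampling distance into G1 (3 axis directions, distance 1), G2
(6 plane diagonals, √2 ≈ 1.414) and G3 (4 space diagonals, √3 ≈ 1.732) — the
three geometric scales the whole method is built around.

Counting requires *both* endpoints of a pair to be in-mask (the stricter
convention; it avoids contaminating lesion texture with surrounding tissue),
and pairs crossing the array boundary are dropped. Matrices are symmetrized
(`C + Cᵀ`) before normalization by default — the classical Haralick
convention; the flag is configurable and recorded.

## The measure registry and descriptor

The measure set is a pluggable ordered registry; the default holds 28
measures: Haralick's canonical 14 (angular second moment, contrast,
correlation, variance, inverse difference moment, sum average/variance/
entropy, entropy, difference variance/entropy, both information measures of
correlation, maximal correlation coefficient) plus 14 standard co-occurrence
extensions (autocorrelation, joint average, cluster tendency/shade/
prominence, dissimilarity, maximum probability, inverse difference and its
normalized variants, inverse variance, marginal entropy, difference energy,
sum energy). Entropy-type measures use natural logarithms with 0·log 0 = 0;
correlation-type measures return 0 when a marginal variance vanishes, so
every measure is finite on every valid matrix. Applied per direction and
concatenated direction-major (G1, G2, G3), the registry yields the
364-variable multi-scale descriptor with contiguous group slices of 84, 168
and 112 variables. Direction-pooled baselines (per-measure mean and range
over all 13 directions) give the traditional 28-feature (14 measures) and
56-feature (28 measures) Haralick sets.

## The hybrid selection model

Stage 1 (per group): features are ranked by random-forest Gini importance
(mean impurity decrease; default 5000 trees; ties break by column order) and
reduced by forward-stepwise feature selection (FSFS): one pass from most to
least important, keeping a candidate only when the mean cross-validated AUC
of the current set strictly improves (configurable `min_improve`, default 0).
The wrapper classifier is a cubic-polynomial-kernel SVM with
gamma = 1/(number of variables), coef0 = 0, tol = 1e−3. Each group ends up
split into its FSFS baseline and a left-over complement.

Stage 2 (hierarchy): the group with the best baseline AUC seeds the
integration; the descriptor pool is [that baseline, remaining whole groups in
descending whole-group AUC, the seed group's complement]. Each level re-ranks
its candidate set by forest importance and runs FSFS against the current
baseline. Strict-improvement acceptance makes the per-level AUC trace
monotonically non-decreasing by construction; with three groups there are
four levels.

Feature scaling: the descriptor mixes scales from ~1e−2 (probabilities) to
~1e6 (fourth-order cluster moments), which a cubic polynomial kernel cannot
absorb numerically. Every SVM fit therefore z-scores its training fold
(scaler fit on training data only) before the kernel; this is the package's
choice and applies uniformly to selection and reporting.

## Evaluation protocol and leakage modes

Reporting uses repeated stratified two-fold cross-validation (default 100
repeats; at n = 63 with classes 31/32 each repeat trains on 31 and tests on
32 samples) with per-repeat test AUC averaged and its STD as the variation
measure; leave-one-out is available as the optimistic bound. Accuracy,
sensitivity and specificity are computed at probability 0.5 on the
logistically squashed SVM margin (0.5 is exactly the decision boundary).

Two modes control where selection sees data:

* **nested** (default): inside every outer repeat, the *entire* selection is
  re-fit on the training half only, with an inner repeated two-fold scheme
  (default 10 repeats) drawn from that half; the held-out half is scored
  once. Reported AUC is untouched by selection, so a label-independent
  dataset scores near 0.5.
* **paper**: selection runs once on the same repeated splits used for
  reporting. This mirrors the original two-stage study protocol and is kept
  for comparability; its reported AUC is optimistically biased because the
  test halves participated in the selection criterion.

Both modes preserve the monotone per-level trace. Method comparisons use the
two-sided Wilcoxon signed-rank test on paired per-sample probabilities (zero
differences dropped; exact null distribution up to 25 nonzero pairs, normal
approximation with continuity correction above).

## The CNN route

The CNN consumes stacked normalized co-occurrence matrices, one channel per
direction (3, 6, 4 channels per group; 13 for the ungrouped comparator). The
network is deliberately small: two blocks of [3×3 conv, 64 maps, stride 1,
same padding → batch norm → ReLU → 2×2 max-pool stride 2], then dense layers
of 1000, 1000 and 2 units with softmax; cross-entropy loss, Adam, initial
learning rate 1e−3 multiplied by 0.01 every 10 epochs, 40 epochs, full-batch
by default (training folds are small). "Same" padding keeps the 32→16→8
spatial reduction aligned with the two pools. The implementation is pure
NumPy (im2col convolutions, explicit backprop, seeded init and batching), so
training is bit-reproducible; analytic gradients are verified against
central differences in the test suite. Group-level integration mirrors FSFS:
the best single group (highest mean AUC) is the baseline and remaining
groups join, in descending individual AUC, only on strict improvement.

## Synthetic data: what it emulates and what it does not

The phantom generator produces the statistical structure the pipeline is
sensitive to, not anatomy. Each sample is Gaussian white noise smoothed to a
target correlation length inside an irregular ellipsoidal mask; benign
lesions are isotropic at a short length (default 1 voxel), malignant lesions
anisotropic (default 4 voxels along one axis). After smoothing, the non-air
in-mask voxels are standardized to exactly the target mean/STD (default
40 ± 100 HU), so first-order intensity statistics carry no class signal and
any classification power must come from second-order structure — precisely
the multi-scale texture contrast the descriptor groups encode. A default 5%
of in-mask voxels are set to −1000 HU to exercise the cleansing step. The
default cohort is 31 benign / 32 malignant, mirroring a small lesion study.

Not emulated: lesion morphology, CT reconstruction physics (noise spectra,
beam hardening, partial volume beyond the injected air), intensity
differences between pathologies, or scanner variation. Passing tests
demonstrate that the machinery recovers planted second-order signal and stays
calibrated under the null; they do not certify clinical performance.

The table generator plants `delta`-STD mean shifts in known columns of
grouped standard-normal tables (a single shifted feature has closed-form
AUC Φ(δ/√2)), giving exact ground truth for selection tests.

## Numerical and scale choices

* Gray levels: 32; quantization bin edges from the in-mask post-cleanse
  range; top edge clipped into the last level.
* Probability matrices sum to 1 within 1e−12; AUC is the rank statistic
  (ties at ½), identical to the trapezoidal ROC area.
* Library defaults keep the reference protocol sizes (100 reporting repeats,
  5000 forest trees). Pipeline entry points and the bundled analysis scripts
  run at desk scale — 5–10 outer repeats, 5–10 inner repeats, 200–500 trees,
  ~40 samples per class — which keeps a full nested run in minutes on one
  core while leaving every structural property identical.
* Determinism: every stochastic component (splits, forests, CNN init and
  batching, phantoms) is driven by explicit integer seeds; repeated runs are
  bit-identical.

## Known limitations

* The exact membership of the original 28-measure set is not public; the
  default registry is a documented, standard 28-measure choice, and all
  structural counts (364/84/168/112/56) hold for any 28-measure registry.
* FSFS is greedy (single pass, no backtracking) — deliberately so; it is the
  method, not an approximation added here.
* Paper-mode reproduces a protocol whose reported AUC is selection-biased;
  it exists for comparability, and nested mode is the default for honest
  numbers.
* The CNN is CPU-oriented; it is sized for cohorts of tens to hundreds of
  samples, not for large-scale imaging.
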