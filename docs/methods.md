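# Methods

## Problem and pipeline

The package grades diabetic-retinopathy severity from fundus photographs by
texture alone.  The working hypothesis is that retinopathy lesions increase
the randomness of the gray-level histogram, so a two-number summary of each
image — Shannon entropy and fuzzy entropy — carries enough signal to
separate a diseased severity level from healthy (NoDR) eyes.  The pipeline
is: duplicate removal, gamma-correction contrast manipulation, entropy
feature extraction, assembly of 16 binary models, a 15-classifier benchmark
with 5-fold cross-validation, and bootstrap validation of the selected
classifier.

## Duplicate removal by structural similarity

Screening collections often contain repeated acquisitions of the same eye;
keeping them inflates apparent sample size and leaks information across
train/test splits.  Duplicates are detected with the structural similarity
index computed from *global* image statistics — one window covering the
whole frame — rather than the sliding-window mean-SSIM used for perceptual
quality scoring.  The global form is the natural choice when the only
decision is "are these the same image?" (SSIM = 1), and it makes the scan
O(pixels) per pair.  Constants are the conventional K₁ = 0.01, K₂ = 0.03
with C₃ = C₂/2 and exponents α = β = γ = 1, under which the three-factor
product collapses to the standard two-factor SSIM; the covariance uses the
unbiased N−1 denominator.  Equality with 1 is implemented as
SSIM ≥ 1 − tol with tol = 10⁻⁹, because floating-point equality is
unreliable while exact pixel copies always clear the tolerance (they are
short-circuited to exactly 1).  Comparisons are made only within a class
label and only between images of equal resolution; the scan removes the
later member of each matching pair and never reuses a removed image as a
keeper, so rerunning the scan on its own output removes nothing.

## Gamma correction

T(u) = (L−1)(u/(L−1))^γ with L = 256 gray levels, applied per pixel on the
grayscale image (luma conversion 0.299R + 0.587G + 0.114B precedes it for
color input).  γ > 1 darkens mid-tones and compresses the dark end of the
histogram; γ < 1 brightens.  The triple γ₁ = 0.9, γ₂ = 1.65, γ₃ = 3 spans
the moderate-contrast band [0.90, 1.65] plus one strongly darkening value,
giving four preprocessing levels per image (original + three corrections).
Rounding is half-away-from-zero, a fixed convention chosen so quantized
outputs are bit-identical across platforms.  Because the map is monotone,
its only effect on a histogram is to move and merge bins — which is exactly
what lets the same entropy statistic respond differently at each level.

## Entropy features

Both statistics are functions of the normalised gray-level histogram p over
the full frame (including the dark border; masking the border would change
absolute values but the classification contrasts are between classes imaged
identically, so the constant border contributes a common offset).

- Shannon entropy SE = −Σ pᵢ log₂ pᵢ, in bits, 0 ≤ SE ≤ log₂ 256 = 8.
- Fuzzy entropy FE = −Σ qᵢ ln qᵢ in nats, with qᵢ = pᵢμᵢ / Σ pⱼμⱼ.

The membership function μ is the genuinely open design point: fuzzy-entropy
definitions in the texture literature fix only that μ involves the mean
gray level and an inclusion threshold ε, not its functional form.  The
default implemented here is a Gaussian membership in gray-level distance
from the mean gray level ī = Σ i·pᵢ, μᵢ = exp(−(i − ī)²/2σ²) with
σ = (L−1)/4 — a standard fuzzy-entropy construction in which levels near
the image's typical brightness count fully and outliers are discounted.  A
uniform membership (μᵢ ≡ 1) is also provided, under which FE reduces
exactly to Shannon entropy in nats; this identity doubles as a test oracle.
ε is read as a low-probability inclusion threshold (bins with pᵢ > ε enter
the sum) with default ε = 0, the least-surprise reading: any positive
default would silently change results.  Log bases follow the conventions
of each statistic: base 2 for SE (configurable), natural log for FE (fixed).

The per-image record is (SE, FE) at each of the four levels — 8 features.

## Model assembly

M1–M16 enumerate severity × preprocessing: M1–M4 mild, M5–M8 proliferate,
M9–M12 severe, M13–M16 moderate, each block ordered O, γ₁, γ₂, γ₃.  A
model's design matrix is a row filter (NoDR + its severity level) and
column projection ((SE, FE) at its level) of the feature table, with labels
NoDR = 0, severity = 1.  The four preprocessing groups {M1,M5,M9,M13} …
{M4,M8,M12,M16} partition the sixteen models; the γ₃ group is
{M4, M8, M12, M16}, the only assignment under which the groups are a
partition consistent with the model definitions.  (Alternative groupings
circulate that repeat M7 in place of M8, or swap the mild and moderate
blocks; both break either the partition property or the model definitions,
so the model definitions above are authoritative here.)

## Classifier benchmark

Protocol: stratified 70/30 train/test split, then stratified 5-fold
cross-validation of every roster family on the 70% portion only; the 30% is
never touched until bootstrap validation.  ("5-fold CV with a 70:30 split"
is sometimes described ambiguously; the training-portion-only reading is
the one that keeps the test set honest.)  Selection is by highest mean CV
accuracy, ties broken by rank AUC and then roster order so selection is
deterministic.  The default split/fold seed is 123, matching the
`random_state = 123` preset of the gradient-boosting family.

The roster is the fifteen families of the standard AutoML comparison:
GaussianNB, random forest (gini, 100 trees), LDA, ridge, k-NN (Minkowski,
k = 5, leaf size 30), extra trees (100), AdaBoost, logistic regression,
LightGBM (gbdt, 100 estimators, 31 leaves), QDA, gradient boosting
(friedman_mse, 100 estimators), XGBoost (gbtree, 100 estimators), decision
tree, linear SVM, and a majority-class dummy as the floor.  Hyperparameters
are fixed presets — no search is performed, since only final values are
specified — implemented via scikit-learn, lightgbm and xgboost with
single-threaded fitting for run-to-run determinism.  QDA carries a small
covariance regulariser (reg_param = 10⁻³) because SE and FE are strongly
correlated (r ≈ 0.95 on synthetic data) and the per-class covariance is
otherwise numerically singular.

Metrics come from the confusion matrix with the severity level as positive:
accuracy, precision, recall, F1, and *two* AUCs reported side by side —
`auc_cm` = 1 − ½(FPR + FNR), the single-threshold confusion-matrix formula
(algebraically balanced accuracy), and `auc_rank`, the usual rank-based
probability that a random positive outscores a random negative (ties ½).
Both are kept because reported metric tables in this field mix the two
conventions.
Rank AUC is undefined (reported as missing, never 0) when the truth has one
class.  Per-fold ratio metrics are averaged over folds; confusion counts
are pooled, so every sample is predicted exactly once per CV run.

## Bootstrap validation

The selected classifier is retrained on B = 100 n-out-of-n resamples (the
classical bootstrap; n is the default convention when no resample size is
specified) of the training portion, each scored on the fixed held-out test
set; the B accuracies and their mean are reported.  A resample containing a
single class is redrawn with a bounded retry budget so the result always
holds exactly B values; at realistic class balance the redraw rate is
negligible.  Each resample's unique-row fraction is recorded as a
diagnostic (expected ≈ 1 − e⁻¹ ≈ 0.632).

## Synthetic data: what it emulates and what it does not

Each image is a dark disc (border fixed at gray level 2) with a smooth
directional illumination gradient, `vessel_count` bright random-walk
strokes, a Poisson(lesion_density · area) number of small bright/dark
Gaussian blobs, and additive Gaussian noise of standard deviation
`noise_sigma`, quantized by clip-then-round-half-away-from-zero.  One RNG
stream seeded from `config.seed` drives the whole call, so equal configs
give byte-identical sets; `inject_duplicates` appends exact pixel copies
with recorded provenance, providing ground truth for the dedup stage.

Default per-class parameters ramp noise_sigma 6 → 10 → 14 → 18 → 24 and
lesion_density 0 → 1.4·10⁻³ across NoDR/mild/moderate/proliferate/severe,
at 64×64 pixels.  No per-class texture statistics are published for real
graded fundus collections, so these values are illustrative: they were
chosen so mean histogram entropy increases monotonically with severity by a
comfortable margin.  A consequence worth stating plainly: at these
conditions the healthy-vs-severe contrast is *fully separable*, and most
benchmark accuracies saturate at 1.0 — higher than any realistic fundus
study, where class overlap keeps accuracies near 0.9.  Passing tests
therefore demonstrate that the machinery is correct (formulas, bookkeeping,
determinism, selection and validation logic), not that entropy features
achieve any particular accuracy on real retinal images.  The generator also
omits optic disc, macula, colour pathology and acquisition artifacts
entirely.

## Numerical choices and degenerate inputs

- Quantization and gamma rounding: half-away-from-zero, then clip to
  [0, 255].
- SSIM of pixel-identical images returns exactly 1 (short-circuit), keeping
  the ≥ 1 − 10⁻⁹ duplicate rule robust to floating-point drift.
- Entropy sums skip empty bins (0·log 0 := 0).  A histogram whose every bin
  is excluded by ε raises a degenerate-input error rather than returning 0.
- Constant images have SE = FE = 0 at every preprocessing level.
- Single-class truths make both AUC variants unavailable, not zero.
- Problem sizes in the test suite and acceptance run (60–150 images per
  class at 64×64) were chosen as the smallest at which the statistical
  checks (KS indistinguishability, binomial null band, bootstrap
  unique-row fraction) are stable.

## Known limitations

- Features are global-histogram statistics: all spatial arrangement is
  discarded, and two images that are pixel permutations of each other are
  indistinguishable (this invariance is tested deliberately).
- The benchmark evaluates each binary model independently; no multi-class
  grading, feature selection across levels, stacking/voting meta-ensembles,
  or hyperparameter search is performed.
- Bootstrap output is the accuracy vector and mean only; no confidence
  intervals or bias correction.
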