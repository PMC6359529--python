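# Methods

## Model and pipeline

SR-MDRM classifies two-class motor-imagery EEG trials through five stages:

1. **Preprocessing.** Trials are bandpassed 7–30 Hz with a fifth-order
   Butterworth filter (the alpha and beta bands carrying ERD/ERS), applied
   forward–backward by default so the epoch is not phase-shifted; a causal
   single-pass mode is available for online-compatible processing. Epochs
   are the half-open window [0.5 s, 2.5 s) after each cue, so a 100 Hz
   recording yields exactly 200 samples per trial.
2. **Covariance.** Each trial is summarized by its trace-normalized
   second-moment matrix `C = XXᵀ/tr(XXᵀ)`. No mean subtraction: bandpassed
   EEG is zero-mean by construction, and trace normalization removes
   per-trial amplitude scale. Per-class composite covariances default to
   the *mean* of trial covariances rather than their sum, so that the
   penalty weight α has the same meaning regardless of how many calibration
   trials a subject has; the literal summed form is available as
   `mode="sum"`.
3. **Spatially regularized CSP.** Filters extremize the class-variance
   ratio with a roughness penalty `α·wᵀKw`, where `K = D − G` is the graph
   Laplacian of the Gaussian electrode adjacency
   `G_ij = exp(−‖v_i−v_j‖²/2r²)`. The diagonal of `G` (all ones) cancels in
   the quadratic form, which equals `½ ΣᵢΣⱼ G_ij (w_i − w_j)²` with both
   indices running over all channels. The 2k filters are the k leading
   eigenvectors of `(C₂+αK)⁻¹C₁` followed by the k leading eigenvectors of
   `(C₁+αK)⁻¹C₂`, each block in descending eigenvalue order; at α = 0 this
   reduces exactly to plain CSP. The non-symmetric eigenproblems are solved
   in their symmetric generalized form (whitening by the penalized
   covariance), which guarantees real eigenpairs; filters are unit-norm
   with the first non-negligible coefficient positive, making the bank
   deterministic under eigenvalue ties.
4. **Geodesic filtering (FGDA).** Projected-trial covariances (2k × 2k) are
   mapped to the tangent space at their Riemannian mean, vectorized (upper
   triangle, off-diagonals weighted by √2 so vector norms equal Frobenius
   norms), projected onto the span of the leading Fisher discriminant
   directions, and mapped back. The operation preserves dimension and
   SPD-ness and is idempotent. The filter is fit on training covariances
   only and applied unchanged to test trials.
5. **MDRM.** One Riemannian (Fréchet) mean per class; a test covariance
   takes the label of the geodesically nearest mean. Ties go to the lowest
   class index with a warning. Accuracy and the chance-corrected kappa are
   computed from the binary confusion counts.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| band | 7–30 Hz | sensorimotor alpha+beta rhythms |
| filter order | 5 | Butterworth bandpass order |
| epoch | [0.5, 2.5) s post-cue | reactive MI window |
| k | 3 | filter pairs; 2k = 6 virtual channels, tangent dim 21 |
| α grid | 10⁻¹⁰ … 10⁻¹ (10 values) | penalty weight |
| r grid | 0.01 … 0.10 (10 values) | kernel width, units of head radius |
| covariance mode | mean | per-class composite (see above) |
| FGDA components | 1 | Fisher directions kept (binary ⇒ 1 nontrivial) |
| FGDA shrinkage | "auto" (Ledoit–Wolf) | within-class scatter regularization |
| CV folds | 5 (LOO if a class has < 10 trials) | hyperparameter selection |

k is not prescribed by the approach itself; 3 pairs is the common CSP
choice and keeps the tangent dimension (21) manageable for FGDA. The r
grid is interpreted in the same normalized units as the montage
coordinates.

**FGDA shrinkage.** The within-class tangent scatter is estimated from as
few as 20 vectors in 21 dimensions, so it must be shrunk toward a scaled
identity before inversion. A small fixed intensity (e.g. 0.05) leaves the
Fisher direction dominated by sampling noise in exactly the small-sample
regime the method targets — in development runs it cost roughly ten
accuracy points relative to disabling FGDA entirely. The default is
therefore the Ledoit–Wolf optimal intensity computed from the pooled
within-class residuals, which adapts from strong shrinkage on tiny
calibration sets to nearly none on large ones; any fixed value in [0, 1]
can still be passed. Setting `fgda_components=None` disables the stage.

**Hyperparameter selection.** The original approach reports per-subject
(α, r) without a selection criterion; this package selects them by
stratified k-fold cross-validation on the training set only (leave-one-out
when a class has fewer than 10 trials), with ties broken toward larger α
then larger r — preferring the smoothest filters among equally scoring
settings. Test trials never enter class-covariance estimation, FGDA
fitting, or the grid search.

## Numerical choices

- All matrix functions go through the symmetric eigendecomposition;
  inputs are symmetrized as `(C + Cᵀ)/2` first, and eigenvalues are
  floored at `1e−12 ×` the largest eigenvalue (with a warning) before
  logarithms or inverse powers, so rank-deficient sample covariances from
  short or few trials do not break the maps.
- The Fréchet mean is the standard fixed-point iteration — tangent-space
  arithmetic mean at the current estimate, exponential map back —
  initialized at the Euclidean mean, with tolerance 1e−8 on the Frobenius
  norm of the whitened tangent mean and at most 120 iterations. The full
  fixed-point step can overshoot on widely dispersed sets, so the step is
  halved whenever the tangent-mean norm grows and relaxed back toward the
  full step while it shrinks; non-convergence returns the last iterate
  with a warning. Members are processed as a batched eigendecomposition,
  which keeps the thousands of small means evaluated during a grid search
  cheap.
- Geodesic distance is computed from the generalized eigenvalues of the
  matrix pair, not an explicit inverse square root.
- The CSP-baseline classifier is Fisher LDA on log-variance features, the
  conventional pairing for CSP.

## Synthetic data: what it does and does not emulate

The generator produces the second-order structure the pipeline consumes:
band-limited (7–30 Hz) Gaussian sources mixed into channels through
spatially smooth patterns (Gaussian-process draws over the montage with
squared-exponential kernel, correlation length `pattern_smoothness`), with
a configurable subset of "discriminative" sources whose power is
`class_variance_ratio` times larger in class 1 — the ERD/ERS analogue —
plus spatially correlated broadband sensor noise at `noise_power`.
Montages are golden-angle spirals on the upper unit hemisphere, so all
spatial scales are in head-radius units. Defaults (ratio 4, noise 0.2,
10 sources of which 3 discriminative, smoothness 0.6) give a clearly
separable but noisy session; ratio 1 gives an exact null. Presets mirror
the three public benchmark scales: 118 channels/100 Hz with a 28/252
train/test split, 60 channels/250 Hz (60/60), 22 channels/250 Hz
(144/144).

Deliberately not emulated: trial-to-trial nonstationarity of background
source power, artifacts (EOG/EMG), volume-conduction biophysics, and
subject-specific spectral peaks. Because the classifier uses only trial
covariances, sources are bandpassed noise rather than parametric
oscillators — second-order realism is what matters. Consequently, passing
tests show that the pipeline recovers planted second-order class structure
at realistic scales and sample sizes; they do not certify accuracy levels
on real recordings, where nonstationarity and artifacts reduce every
method's headroom. Under the default generator conditions the
small-sample comparison between SR-MDRM and full-dimension MDRM saturates
(both near-perfect); the hard-session examples use ratio 2 with noise 2.0
to show non-trivial behavior.

## Problem sizes

The test suite and `scripts/acceptance.py` use sessions of 16–118 channels,
20–288 trials, and 2 s epochs at 100–250 Hz; the small-sample study runs 20
replicates of the 60-channel / 20-trial regime with a 4 × 3 (α, r)
subgrid of the default grids, while the benchmark-scale runs use the full
10 × 10 grid. These sizes exercise every regime the method distinguishes
(rank-deficient class covariances included) while keeping a full run in
the minutes range on one core.

## Known limitations

- Binary classification only; the evaluation metrics are defined on 2 × 2
  confusion counts.
- The Fréchet mean is recomputed in batch; no online update when new
  calibration trials arrive.
- Electrode coordinates are taken at face value; no template lookup by
  channel name is provided (montage files must carry positions).
- FGDA component count and shrinkage interact with calibration-set size;
  the Ledoit–Wolf default is a good compromise but geodesic filtering can
  still cost accuracy on very small calibration sets (disable it via
  `fgda_components=None` to check).
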