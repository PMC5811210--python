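# Methods

`repdyn` implements a complete analysis chain for epoched multichannel
neural time series from a task-cued object-recognition experiment:
time-resolved multivariate decoding, temporal generalization,
representational similarity analysis (RSA), model-based MEG-fMRI fusion by
commonality analysis, and the nonparametric statistics that accompany them.
Because no recordings ship with the package, a synthetic-data generator
with known ground truth is a first-class module: every downstream stage is
validated by recovering what the generator injected.

## The experimental model

Trials follow a 4-task x 8-category x 5-exemplar x 2-color x 2-tilt
factorial design: 160 unique stimuli, each shown once per task, giving 640
experimental trials in 20 runs of 36 (32 experimental + 4 catch; catch
trials are random task/stimulus combinations and are excluded from every
analysis by default — their analysis fate is a package choice).  Epochs run
from -100 ms to 5000 ms around the task cue; the object stimulus appears at
2000 ms and the response-mapping screen at 3500 ms.  Tasks 0-1
("color", "tilt") are perceptual, tasks 2-3 ("content", "size") conceptual.

## Synthetic data

Each trial is

    x(t) = a_T * p_task(task) * e_T(t) + a_O * g(t) * p_cat(category) * e_O(t) + n(t)

with unit-norm spatial patterns `p` drawn once per `pattern_seed`,
smoothed-boxcar amplitude envelopes `e` (half-cosine 10 ms edges starting
*at* the onset, so no pre-onset energy), white Gaussian sensor noise
`n ~ N(0, noise_sd^2)` and a task-type gain `g(t)` that scales object
patterns on conceptual-task trials from a configurable latency.  Defaults:
task onset cue + 100 ms (envelope sustained to the epoch end), object onset
stimulus + 80 ms (1 s duration), amplitudes 1.0 against unit noise, gain 1
(off).  The desk scale is 64 channels, 300 Hz, 10 subjects; 272 channels /
1200 Hz / 17 subjects are available by configuration.

fMRI-like ROI patterns mix a task component, an object component and unit
noise per condition: `w_T u_task + w_O v_cat + sd * eps` over `n_units`
units, where `u`/`v` are orthonormal, mean-zero basis vectors scaled to
unit per-unit SD so the three coefficients share one scale.  With zero
noise the induced 1 - Pearson RDM *equals* the binary model RDM of the
dominant factor; with both weights the RDV correlates with each model in
proportion to the squared weight.

What the generator does **not** emulate: forward head models and realistic
sensor covariance (noise is white), 1/f spectra, eye blinks or other
artifacts, behavioral variability, inter-subject pattern variability
(patterns are shared across simulated subjects — immaterial for
within-subject decoding, coherent for group RDMs).  Passing tests therefore
demonstrate the correctness and calibration of the *analysis machinery*,
not performance on real recordings.

## Preprocessing

Order: filter -> spatial PCA -> component pruning -> baseline
normalization -> temporal smoothing -> downsampling.  Each step is a pure
function of data + configuration.

- **Filtering**: zero-phase Butterworth band-pass (default 0.1-300 Hz)
  plus 60 Hz notches at every harmonic below Nyquist.  The desk preset sets
  the lower edge to 0 (low-pass + notch only): a zero-phase high-pass
  applied to 5.1 s epochs redistributes the DC content of sustained evoked
  envelopes into the pre-onset baseline (we measured ~64% pre-cue task
  decoding from this artifact alone), and drift-free synthetic data gains
  nothing from a high-pass.  On real recordings, filter continuous data
  before epoching instead.
- **Spatial PCA** is fit on all trials concatenated in time; it is a pure
  channel-space rotation (no temporal mixing), implemented by
  eigendecomposition of the channel covariance.  Component scores are kept
  in single precision.
- **Pruning** removes the largest ascending-variance suffix of components
  whose summed variance is at most 1% of the total, capped at half the
  components (the cap binds for a 272-channel array, retaining 136).  The
  1% rule is read cumulatively, not per-component.
- **Baseline normalization** ("univariate noise normalization") z-scores
  each component against baseline statistics pooled over all trials'
  baseline samples (pooled rather than per-trial, for stability; the window
  is -100..0 ms for task analyses and 1900..2000 ms for object analyses,
  and the choice is recorded in provenance and enforced at decoding time).
  A zero-SD component is an error naming the component.
- **Smoothing** uses a unit-sum Gaussian with half-duration-at-half-maximum
  15 ms (FWHM 30 ms, sigma = 30/(2 sqrt(2 ln 2)) ~ 12.74 ms), truncated at
  4 sigma with reflected edges; **downsampling** keeps every k-th smoothed
  sample from the epoch start and requires an integer rate ratio (desk:
  300 -> 60 Hz; paper scale: 1200 -> 120 Hz, 6120 -> 612 samples under this
  convention).

## Time-resolved decoding

One iteration: per class, trials are randomly partitioned into disjoint
groups of 10 and averaged into supertrials (remainders unused that
iteration); one supertrial per class is held out; for each unordered class
pair and each time point an independent linear SVM (C = 1, hinge loss,
bias as an augmented constant feature) is trained on the remaining
supertrials.  The held-out pair is scored by **ordering accuracy**: 100 if
the positive-class sample's decision value exceeds the negative-class
sample's, 0 if reversed, 50 on a tie — for one sample per class this is
exactly the two-sample ROC AUC and is independent of the bias term.  The
lexicographically first class of a pair is the positive class.  Pair scores
are averaged (28 pairs for categories, 6 for tasks; chance 50%) and the
curve is the mean over iterations (paper scale 500; desk 30-50).  Each
iteration draws its RNG stream from (seed, iteration), so iterations are
independent and order-insensitive.

The SVM is solved by dual coordinate descent over precomputed Gram
matrices, JIT-compiled and batched over time points; it optimizes the same
objective as liblinear's dual L1-loss SVC with bias augmentation, and the
test suite verifies agreement with `sklearn.svm.LinearSVC(loss="hinge")`
to ~1e-6.

**Temporal generalization** evaluates every training-time classifier at
every testing time on the same held-out supertrials.  **Cross task-type
decoding** builds supertrials separately within perceptual and conceptual
trials, trains within one type, and tests on held-out supertrials of the
same type (within) or the other type (between), averaged over directions.

A property worth knowing: because supertrials *partition* a class's
trials, the held-out supertrial's composition with respect to any other
factor (e.g., task, for category decoding) is anti-correlated with the
training supertrials' composition.  When a strong shared signal varies
along that other factor, held-out ordering accuracy falls systematically
*below* 50% at those times (we observe ~40% for category decoding during
task-signal-only periods).  This is inherent to hold-out-supertrial schemes
with fixed per-class totals, affects the within-task-type condition
slightly more than between, and is harmless for the one-sided above-chance
tests used throughout.  A much weaker cousin of the same effect exists
even on pure noise (the PCA's global mean couples all trials at -1/N),
leaving noise-floor accuracy ~0.3 percentage points below 50% — well
inside the +/-1 point calibration band.

## RSA

Condition patterns are the mean component vectors per (task, category)
cell — 32 conditions in a fixed task-major ordering embedded in every
artifact and verified (never assumed) by cross-modal operations.
Dissimilarity is 1 - Pearson r; RDMs are symmetric with a zero diagonal;
the RDV is the column-major lower triangle excluding the diagonal (496
entries).  Model RDMs are binary (0 = same factor level).  The task and
category model RDVs correlate at -sqrt(2)/8 ~ -0.177 by design, so the
fusion regression must (and does) handle non-orthogonal models.

## Model-based fusion and commonality analysis

For MEG RDV `X_t` and ROI RDV `Y_j`, total fusion is the squared Spearman
correlation R²(X_t, Y_j).  The commonality of model A (task) given model B
(category) is

    C(X_t, (Y_j, A)) = R²(X_t, Y_j.B) - R²(X_t, Y_j.A,B)

where `Y.B` denotes Y's ranks residualized on B's ranks (least squares,
with intercept); the squared semi-partial correlations use
rank-then-residualize order with average tie-ranking (binary model RDVs are
massively tied, so the tie policy matters).  Commonalities are reported
unclipped: they can slightly exceed R² or go slightly negative under
suppression or numerical error.  The default target variable is MEG
(models partialled out of the fMRI RDV); a flag switches the target, and no
equality between the two targets is asserted.  A zero-variance residual
(Y fully explained by the partial set) defines the semi-partial R² as 0
with a warning.

## Statistics

- **1D sign-permutation cluster test**: subtract chance; enumerate all 2^n
  subject sign assignments when 2^n <= 131,072 (n = 17 gives exactly
  131,072), else sample distinct assignments with the identity always
  included.  The cluster-inducing threshold is the per-time 95th percentile
  of the permutation t distribution; clusters are maximal supra-threshold
  runs; the cluster statistic is extent in samples.  Significance uses the
  exact permutation p-value `P(null max size >= observed size) <= alpha`
  (one-sided).  With integer extents this is the calibrated form of
  "size >= 95th percentile of the max-size null": the quantile form is
  anti-conservative under heavy ties, the exact form guarantees
  FWER <= alpha and measures 0.028 at desk-length curves (500 null
  simulations, n = 17, alpha = 0.05).
- **2D extension** for generalization matrices uses 4-connectivity
  (edge-adjacent; diagonal touching points are separate clusters) and a
  fixed number of distinct sampled permutations (paper scale 10,000).
- **Fusion randomization test**: there is one group-average MEG RDM
  series, so the null permutes condition labels (the same permutation of
  rows and columns at every time point, preserving symmetry and zero
  diagonal), reruns the fusion, and pools the max-cluster-size null across
  ROIs as multiple-comparison correction (paper scale 5000 permutations).
- **Bootstrap latency CIs** resample subjects with replacement, average
  (for fusion: average the resampled MEG RDM stacks, then rerun fusion),
  extract the latency statistic (argmax for peaks; paired argmax difference
  for peak differences; first criterion crossing for onsets — the onset
  criterion is a package definition, stated as such), and take
  closest-observation 2.5/97.5 percentiles, so CI endpoints lie on the
  sampled time grid and are conservative by up to two sample periods
  (16.67 ms at 120 Hz).  A flat curve falls back to the earliest maximum
  and is flagged.

Degenerate inputs: zero-variance samples in t statistics map to a large
finite capped value (so thresholds stay well defined); zero-variance
patterns, constant RDVs and asymmetric RDMs are errors.

## Scale presets and problem sizes

The `desk` preset — 10 subjects, 64 channels, 300 Hz -> 60 Hz (306 samples
per epoch), 30 decoding iterations, temporal generalization with 10
iterations on a 3x-decimated grid, exhaustive sign permutations at n = 10,
500 RDM randomizations, 2000 bootstrap draws — runs the full chain on one
CPU in minutes and is what the test suite exercises.  The `paper` preset
mirrors a full study (17 subjects, 272 channels, 1200 -> 120 Hz, 500
iterations, 10,000/5000 permutations, 100,000 bootstrap draws) and is
provided for completeness; it is compute-hungry by design.  Pipeline
outputs are deterministic given (configuration, seed): per-stage seeds are
derived from the global seed and stage name, and the result bundle records
SHA-256 checksums and the stage provenance graph.

## Known limitations

- The generator's white, spatially uncorrelated noise makes decoding far
  easier than real MEG at matched amplitude; effect sizes here say nothing
  about empirical effect sizes.
- Condition-label permutation tests assume exchangeability of condition
  labels under the null, which the generator satisfies by construction.
- Filtering operates on epochs, not continuous data; see the high-pass
  note above.
- Onset latency via criterion crossing is a pragmatic definition; peak
  latencies are the better-behaved statistic on this grid.
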