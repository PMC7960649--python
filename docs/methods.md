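# Methods

This note records the models, defaults, and numerical choices behind
mvpakit, and what the synthetic benchmark does and does not establish about
real data.

## Job model

A job is one JSON object with exactly four sections — `model`, `data`,
`analysis`, `output` — mirroring the four runtime responsibilities
(classifier construction, data handling, cross-validation orchestration,
result writing). The legal key set of each section is defined by the
packaged `schema.json` and is this package's own dialect. Unknown keys
*inside* a section are warnings, not errors, so job files written for a
later version still validate; an unknown top-level section is a hard error
because it indicates a structural mistake. Serialization is canonical
(sorted keys, 2-space indent) so that the job copy saved with the results is
byte-identical across repeated runs and diffs cleanly between analyses.

## Data handling

Data are an N-d numeric array with examples on axis 0 plus named per-example
sample attributes; attribute vectors must match the example count and
non-finite data values are rejected at load time. Containers are `.npz`
(named arrays) and `.mat` in both the classic v5 dialect (read via
scipy.io) and the HDF5-backed dialect (read via h5py, transposing
datasets that carry MATLAB class attributes, since MATLAB stores
column-major). A bare `.npy` cannot carry attributes and is rejected with a
pointed message. Custom loaders are plain callables registered by name or
imported from a user-named `.py` file.

Classical models see examples flattened row-major to 2-D; the deep backend
sees full-rank examples so that convolutional filter shapes keep their
spatiotemporal meaning.

### Cross-validation

- `single`: test and validation counts are round-half-to-even of
  n·fraction; the training set takes the remainder (or its own rounded
  count when the fractions deliberately sum to less than 1). Rounding ties
  to even keeps sizes deterministic and summing to n.
- `loop_over_sa`: one split per sorted distinct value of the grouping
  attribute. The attribute's reading is ambiguous between two useful
  designs, so both are offered behind a `loop_mode` flag:
  `leave_group_out` (default — the named use case is leave-one-subject-out:
  test on the group, train on everyone else, validation carved from the
  training pool by the validation fraction) and `within_group` (split each
  group's own examples by the fractions).
- Splits are *not* stratified by class; with the balanced datasets the
  benchmark produces, per-iteration class imbalance in a 5–15% test set is
  minor, and unstratified splitting is the simpler contract.

Per-iteration seeds derive from `SeedSequence([master_seed, counter])`,
giving independent, reproducible streams; the master seed is recorded in the
run metadata.

### Rescaling

All four methods fit statistics on the training partition only:

| method | transform | fitted stats | user params |
|---|---|---|---|
| `percentile` | x / Q_p(train) | Q_p (linear interpolation) | `p`, required explicitly |
| `standardize` | (x − mean) / sd | mean, sample sd (n−1) | — |
| `mean_center` | x − mean | mean | — |
| `map_range` | lo + (x − min)(hi − lo)/(max − min) | min, max | `lo`, `hi` (default 0, 1) |

Values outside the training range after `map_range` fall outside [lo, hi] by
design (no clipping): clipping would silently distort test data. Statistics
are computed globally over all elements of the training partition; whether
per-feature scaling is preferable depends on the data, so a `per_feature`
flag is offered (default off, and the global default is a documented choice,
not a claim about any other implementation). Degenerate scales (zero sd,
zero percentile value, min = max) raise immediately rather than producing
infinities downstream.

## Classifiers

### SMLR

The package's own algorithm. Objective over augmented weights
W ∈ R^{(d+1)×K} (row 0 = bias, unpenalized):

    f(W) = (1/n) Σᵢ −log softmax(xᵢW)[yᵢ] + λ Σ_{j≥1,k} |W_{jk}|

minimized by ISTA: gradient step on the smooth part, soft-threshold on the
penalized rows, backtracking line search against the quadratic majorization,
with the step allowed to grow back between iterations. Convergence when the
objective decrease over an accepted step falls below `tol` (default 1e-9);
hitting `max_iter` flags `converged=False` on the result instead of
raising, because a near-converged model is still usable. λ defaults to 0.1
(the packaged sample job uses 0.01, which suits the benchmark's feature
scale). The mean (rather than summed) likelihood makes λ comparable across
dataset sizes. For K = 2 the penalized optimum is attained at an
antisymmetric weight split (±δ/2 per class column, total penalty λ|δ|),
which is what the brute-force grid oracle in the test suite exploits.

### SVM

Linear kernel, C = 1 unless overridden. Multiclass is one-vs-rest over
explicit per-class binary machines (scikit-learn's libsvm binding does the
binary optimization); scores are the K decision values, deliberately left
unnormalized since hyperplane distances are not probabilities.

### Deep backend

A numpy sequential-network engine, deliberately small: layers are dense,
conv (1-D or 2-D valid-mode filter banks, stride 1, channels last), a
simple-recurrent (Elman, tanh) cell that consumes a (timesteps, features)
example and emits its final hidden state, dropout (inverted, train-time
only), flatten, activation, and non-overlapping average pooling. Gated
recurrent variants and non-sequential graphs are out of scope.

Defaults follow small-decoding-network practice: leaky ReLU slope 0.3,
dropout 0.3, SGD with Nesterov momentum 0.9; Adam available. Training is
mini-batch (default batch 32) categorical cross-entropy for a default 50
epochs; the terminal softmax is fused with the loss for numerical
stability, and an intermediate softmax is rejected at build time. Weight
init is Glorot uniform. One seeded generator drives initialization, batch
shuffling, and dropout, and everything is single-threaded numpy, so runs
are bit-reproducible; there is no accelerated mode. A NaN/Inf loss raises
immediately with the offending epoch/batch and logit range. The validation
partition is monitored per epoch but never drives early stopping or
parameter selection — the leakage-safety contract stays trivial to audit.

Build-time checks name the offending layer: dense on un-flattened input,
kernel rank exceeding the input rank, final width ≠ n_classes.

## Outputs

TSVs: UTF-8, header row, tab separator, no quoting. Accuracy and loss
columns use the shortest round-trip float repr so that
`summarize_accuracy(write_outputs(bundle))` reproduces the bundle mean
bit-for-bit; score and timestamp floats use 6 significant digits for
readability. The `"all"` token expands to every kind except the specialized
`model` export (a `.npz` of architecture JSON + weight arrays, requested
explicitly). Score rows are (iteration, example_index, true_label,
score_class_0..K−1). Single-iteration accuracy files summarize with
sd = sem = 0 and an explicit n = 1 so downstream tools can exclude them.

## Synthetic benchmark

Per condition c: canonical pattern s_c ~ N(0, I) over features; m = √T
variations v = (1−α₁)s_c + α₁ε; each variation spawns m sub-variations
w = (1−α₂)v + α₂ε′, one per trial; final trial =
(1−(K−1)β)·w + β·(one random sub-variation from each other condition).
This mimics a condition having a few "true" pattern variants plus
trial-level exemplar/measurement variation, with cross-condition blending to
keep accuracies moderate.

Choices where the construction was open, fixed once:

- All signals and noise i.i.d. standard normal per feature — the simplest
  stationary choice.
- Defaults α₁ = α₂ = 0.5, β = 0.15 (β must satisfy (K−1)β < 1, and < 0.5
  per other condition): strong enough hierarchy to decode well above chance
  at 200 features, enough cross-blending that accuracy is not trivially 1.0
  at small trial counts.
- Cross-condition blending uses the other conditions' *pre-mix*
  sub-variation signals, not finalized trials, avoiding a circular
  definition of the trial set.
- Trials are emitted condition-major then variation-major; the ordering is
  part of the fixture contract.

The generator is *not* biologically realistic: no hemodynamics, spatial
smoothness, channel covariance, or temporally autocorrelated noise.
Passing tests on it therefore establish pipeline correctness (leakage
safety, seeding, scoring, chance-level behavior on label-independent data,
above-chance behavior when structure exists) — not expected accuracy levels
on real recordings.

The full sweep definition crosses 8 feature counts (200·2^k, k = 0..7) with
10 trial counts ((10k)², k = 1..10), three conditions, 80 configurations,
ordered by (features, trials).

## Problem sizes in the test and acceptance suites

Statistical checks run on the 200-feature, 100-trials/condition dataset
(300 trials total): chance-level and above-chance decoding use 20
cross-validation iterations of the packaged jobs, pooling 300 (classical,
5% test) or 900 (deep, 15% test) test predictions, compared against the
two-sided 99% normal-approximation binomial interval around 1/3. The SMLR
grid oracle refines a 101×101 grid over (w, b) ∈ [−5, 5]² through 9 zoom
rounds (final resolution ~10⁻⁸). These sizes keep the whole suite at about
a minute while leaving the statistical margins wide.

## Known limitations

- Conv layers support stride 1, valid padding, and 1-D/2-D kernels only; a
  1-D kernel cannot be applied to a multi-channel 2-D feature map.
- The recurrent cell is ungated; long sequences will hit vanishing
  gradients.
- SMLR's ISTA can need many iterations at very small λ and tight `tol`;
  the result object's `converged` flag should be checked for production use.
- Classical `.mat` string cell arrays beyond simple char vectors are not
  exhaustively handled; prefer numeric attribute codes in containers.
- `loop_over_sa` assumes the grouping attribute is categorical with a
  modest number of values; it materializes one model per (group, iteration).
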