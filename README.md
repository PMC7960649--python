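# mvpakit

Config-driven multivariate pattern analysis (MVPA) and its deep-learning
variant (dMVPA) for trials-by-features neural-style data — fMRI voxel
patterns, EEG channel-by-timepoint arrays, eye-tracking features, or any
dataset whose first axis indexes examples.

One declarative JSON job file fully specifies an analysis: which data file
and loader to use, how trials are divided into training/validation/test sets
across cross-validation iterations, how the data are rescaled without
leaking test-set statistics, which classifier is trained (a classical linear
SVM or sparse multinomial logistic regression, or a small sequential neural
network), and which result files to save. The job file doubles as the
provenance record: a canonical copy is written next to the results, so rapid
model exploration never loses track of what produced which numbers.

It is aimed at cognitive-neuroscience researchers who want to compare
classical decoding against small neural networks on the same data with
identical data handling, and at anyone who wants a fully reproducible,
seeded decoding pipeline driven by plain-text configuration.

## The core pieces

**Cross-validation.** Two schemes: `single` pools all trials and randomly
splits them by (train, val, test) fractions each iteration; `loop_over_sa`
iterates over the values of a grouping sample attribute (e.g., subject
identity) — either leave-group-out (test on the held-out group) or
within-group. Every iteration trains a freshly initialized model.

**Leakage-safe rescaling.** `percentile`, `standardize`, `mean_center`, and
`map_range` all fit their statistics on the training partition only and
apply them unchanged to validation/test data.

**SMLR.** Sparse multinomial logistic regression, authored here: for class
scores `softmax(x W)` with weights `W ∈ R^{(d+1)×K}` (bias row unpenalized),
it minimizes

    f(W) = (1/n) Σᵢ −log softmax(xᵢW)[yᵢ] + λ Σⱼₖ |Wⱼₖ|

by proximal gradient (ISTA) with backtracking; soft-thresholding drives
uninformative weights exactly to zero.

**SVM.** Linear kernel, `C = 1` by default, multiclass assembled one-vs-rest
from binary machines (scikit-learn under the hood); per-class scores are the
binary decision values.

**Deep backend.** A compact numpy sequential-network engine: dense, conv
(1-D/2-D filter banks on full-rank examples), simple-recurrent, dropout,
flatten, activation (leaky ReLU with slope 0.3 by default), and average-pool
layers; SGD with classical/Nesterov momentum (default 0.9) or Adam;
categorical cross-entropy loss. Single-threaded and bit-reproducible given a
seed.

**Decisions and scoring.** Every model emits per-example, per-class scores;
the categorical decision is winner-take-all (argmax, ties to the lowest
class index). Raw scores are exported so that ROC-style analyses can be done
downstream.

**Synthetic benchmark.** A generator for three-condition fMRI-like datasets
with hierarchical signal structure: per condition, a canonical pattern spawns
√T noise-blended variations, each spawning √T sub-variations (one per
trial); each trial is finally blended with a random sub-variation from every
other condition to make classification harder. A pure-noise control
generator produces data whose labels are provably uninformative. The full
benchmark grid crosses feature counts 200–25,600 (doubling) with
trials/condition 100–10,000 (squares progression).

## Worked example

Generate a benchmark dataset, run the packaged classical job (10 iterations,
95% train / 5% test, standardize rescaling, SMLR with λ = 0.01), and
summarize:

```sh
mvpakit synth --features 200 --trials-per-condition 100 --seed 1 \
    --out benchmark_small.npz
python -c "from mvpakit.job import load_sample_job, write_job_copy; \
    write_job_copy(load_sample_job('classical_smlr.json'), 'job.json')"
mvpakit run job.json
mvpakit summarize results/classical_smlr_test_accuracy.tsv
```

prints

```
wrote benchmark_small.npz (300 examples x 200 features)
job.json: mean test accuracy 0.9733 over 10 iteration(s)
results/classical_smlr_test_accuracy.tsv  n=10  mean=0.973333  sd=0.0344265  sem=0.0108866
```

Each of the 10 cross-validation iterations held out 15 of the 300 trials;
the mean test accuracy of 0.973 (sd 0.034 across iterations, sem 0.011) is
far above the 1/3 chance level for three balanced classes, as expected for
the default blend settings, which leave a strong condition signal. The
`results/` directory also gains scores, labels, train-accuracy, timestamp,
and metadata TSVs plus the canonical job copy. The same data can be decoded
with the packaged deep job (`deep.json`: a conv → dense → dropout → dense
softmax stack, 20 iterations, 70/15/15 split) for a like-for-like
classical-vs-deep comparison.

As a library, the same run is three calls: `generate_benchmark(...)`,
`run_job(load_sample_job("classical_smlr.json"), dataset=...)`, and
`write_outputs(...)`.

## Not in scope

GUI job editors, vendor neuroimaging formats (NIfTI/EDF/BrainVision readers),
preprocessing (filtering, artifact rejection), GPU kernels, non-sequential
network graphs, nested hyperparameter search, and significance testing of
accuracies. See `docs/methods.md` for the model details, parameter defaults,
and known limitations.
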