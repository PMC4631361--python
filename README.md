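# depthmvpa

Decode near/far depth positions from ROI voxel patterns and test whether
decoding accuracy tracks behavioral performance. The package implements a
complete, fully synthetic analogue of an event-related fMRI depth-judgment
experiment:

- **design** — trial sequences balanced for one-trial-back history (a random
  Eulerian circuit over the complete condition digraph with self-loops, plus
  a dummy first trial) and exact trial timing (3 s trials, 9 s fixation
  bookends, 3:1 split of 1.2 s / 1.4 s response-cue delays).
- **psychometrics** — cumulative-Gaussian performance curves with guess and
  lapse asymptotes: maximum-likelihood fitting, analytic thresholds,
  simulated binomial observers, linear or log stimulus axes.
- **synthetic_data** — ROI voxel time series with disparity-selective voxels
  whose near/far response difference scales with signal level through a
  configurable coupling, a nonselective stimulus response, hemodynamic delay
  as a 3-volume shift, slow drift, and Gaussian noise; plus per-trial
  behavioral responses drawn from a psychometric observer.
- **preprocess** — high-pass filtering (3 cycles/run) with linear detrending,
  hemodynamic shift, voxel ranking by a stimulus-vs-fixation t statistic
  (top 300 positive-t voxels), per-trial pattern extraction, (4, 4, 3) trial
  averaging into 3 patterns per condition per run, per-run z-scoring, and
  per-pattern mean subtraction.
- **decoding** — linear SVM (cost = n_folds / sum of squared training data)
  with leave-one-run-out cross-validation, trained at the highest signal
  level and tested at every level (6 test patterns per level per fold).
- **nulls** — permutation null distributions (999 shuffles of the training
  labels), nearest-rank centiles, the upper 99.5th-centile significance
  criterion, and the 32nd–68th-centile chance band.
- **fmrmetric** — cumulative-Gaussian fits to decoding accuracies with the
  lower asymptote constrained to the chance band (free fit), the
  behavior-scaled fit (location/slope carried over, asymptotes fitted by
  least squares), Pearson goodness-of-fit, and accuracy-vs-level saturation
  regression.
- **report / cli** — a config-driven pipeline orchestrating all stages with
  seeded determinism, config hashes in every output, and TSV/JSON artifacts.

## CLI

```sh
# balanced event table: 11 conditions x 11 reps (121 trials + dummy, 384 s)
depthmvpa design --conditions 11 --reps 11 --seed 1 --out events.tsv

# full pipeline from a config (two synthetic ROIs: coupled + null)
depthmvpa report --config configs/demo.yaml --out out/

# a fast smoke run
depthmvpa report --config configs/smoke.yaml --out out_smoke/
```

Individual stages are exposed as `simulate`, `preprocess`, `decode`,
`null`, and `fit` subcommands; each reads/writes plain TSV + JSON so every
stage can be re-run independently.

## Layout

```
src/depthmvpa/       one module per pipeline stage
tests/               pytest suite; tests/test_acceptance.py holds the
                     acceptance criteria (design arithmetic, pattern
                     bookkeeping, null calibration, parameter recovery,
                     oracle equivalences, end-to-end discrimination)
scripts/acceptance.py
configs/             demo.yaml (full-scale), smoke.yaml (seconds)
```
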