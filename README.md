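# c8fate

Single-cell analysis of initiator-caspase (C8) activation dynamics and
death-receptor-induced cell fate.

## The problem

When a clonal cell population is exposed to TRAIL or other agonists of the
death receptors DR4/5, only a fraction of the cells dies — even at saturating
dose.  Live-cell imaging with an initiator-caspase FRET reporter shows that
each cell's reporter ratio FR(t) rises after a lag as C8 becomes active at
the death-inducing signaling complex, and that the *rate* and *duration* of
this activation, not the accumulated total, decide the cell's fate.

`c8fate` implements that analysis as a reusable Python library for anyone
studying apoptosis dynamics in single-cell reporter time series:

- **model fitting** — per cell, fit the phenomenological model

  ```
  FR(t) = k (t − t0)²            (activation phase, t0 ≤ t ≤ τ)
  C8 activity = dFR/dt = 2k (t − t0)
  Max(C8) = 2k (τ − t0)
  ```

  with the protocol constraints (t0 ∈ [−30, τ−30] min, k ∈ [0, 0.01],
  F-test vs a flat model at P = 0.05 with a floor rate k = 10⁻⁷ for
  non-responders, retry on secondary derivative maxima when r² < 0.5);

- **threshold estimation** — find the death threshold θ on Max(C8) by
  minimizing the live/dead misclassification count, and classify cells with
  the fate boundary **τ = θ/2k + t0**, benchmarked against a linear SVM;

- **population statistics** — geometric-mean k, surviving fractions,
  the logistic dose–response of survival vs mean log₁₀(k), and rank
  statistics for resistance-factor analyses;

- **a calibrated synthetic-data generator** — lognormal cell-to-cell
  variability in k, τ−t0 and the per-cell threshold, calibrated in closed
  form to published population anchors (50% killing at 25 ng/ml, 4→92%
  killing and a 140-fold GM-k span from 1→500 ng/ml, 83% threshold
  accuracy, θ = 2.63×10⁻³), so the full pipeline is testable without any
  imaging data.

## Worked example

`examples/` contains one short script per capability.  For instance,
estimating the threshold and comparing fate classifiers on a synthetic
half-killing cohort (`python examples/03_threshold_and_boundary.py`):

```
300 fitted cells, 47% died
theta_hat = 0.00226 a.u./min (threshold accuracy 85.0% +/- 1.9%)
fate-boundary accuracy  = 85.3%
linear SVM accuracy     = 85.0%
```

`theta_hat` is the single cutoff on peak C8 activity that best separates
dying from surviving cells; its accuracy is limited by cell-to-cell
threshold heterogeneity, and the analytic fate boundary (one threshold plus
the 20-min population-mean lag) classifies as well as a data-driven
max-margin line.  The other examples calibrate and simulate dose ladders
(`01`), fit a single trajectory against ground truth (`02`), and fit the
logistic dose–response (`04`).

A thin CLI wraps the same pipeline:

```bash
c8fate simulate --dose 25 --n 300 --seed 1 --out data/
c8fate run-all --dose 10 --dose 25 --dose 100 --n 300 --out runs/r1
```

## Layout

```
src/c8fate/
  calibration.py   closed-form calibration of the population model
  simulate.py      synthetic trajectory generator
  preprocess.py    smoothing, derivative, tau location
  fitting.py       constrained quadratic fit, F-test, fallback
  threshold.py     theta estimation, fate boundary, SVM benchmark
  popstats.py      condition summaries, logistic dose-response, rank stats
  experiments.py   reference in-silico experiments
  pipeline.py      end-to-end orchestration and tabular IO
  cli.py           thin command-line interface
docs/methods.md    model, assumptions, numerical choices, limitations
```
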