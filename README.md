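# coxbench

Benchmarking pipeline for Cox proportional-hazards estimation strategies in
**low events-per-variable (EPV)** settings.

Prognostic survival models are routinely built with the Cox model
h(t) = h0(t)·exp(β′x), but when observed events are scarce relative to the
number of candidate predictors — EPV below the conventional 10–20 — the
standard partial-likelihood fit and p-value-driven variable selection
become unreliable: coefficients inflate, selection turns unstable, and
predicted risks are poorly calibrated.  Penalized estimation (ridge, lasso,
elastic net) trades a little bias for a large variance reduction and is the
usual remedy.  `coxbench` exists to *measure* that trade-off: it simulates
cohorts from a known Weibull proportional-hazards truth, censors them to an
exact target EPV, fits six estimation strategies, and scores each against
the truth it was trying to recover.

It is aimed at biostatisticians and methods researchers who want a
reproducible, fully seeded harness for comparing Cox estimation strategies
under event scarcity — either on the built-in synthetic cohorts (a
clinical + biomarker block, optionally plus 55 allele-dosage variants) or
on their own delimited survival tables.

## The core quantities

* Truth: S_i(t) = exp(−rate·t^shape·exp(x_i′β)), simulated by inverse
  transform T = (−log U / (rate·e^{x′β}))^{1/shape}, censored at
  U(0, δ) with δ solved analytically so that E[#events] = EPV × p.
* Strategies: full partial-likelihood Cox; backward elimination at
  α = 0.05 and 0.5; ridge, lasso and elastic net maximizing
  (2/n)·l(β) − λ[a‖β‖₁ + (1−a)/2‖β‖₂²] with λ (and a) tuned by
  cross-validated partial log-likelihood; backward elimination followed by
  a ridge refit of the selected predictors.
* Scores vs truth: RMSE(t) = √(mean_i (S_i(t) − Ŝ_i(t))²); calibration
  slope α₁ (OLS slope of true on predicted event log-odds; 1 is ideal,
  < 1 overfitting, > 1 over-shrinkage); concordance (share of pairs ranked
  consistently with the truth, τ = 2(c − ½)).

See `docs/methods.md` for the full model description, defaults and
numerical choices.

## Worked example

One simulated scenario-1 dataset at EPV 2.5 (9 candidate predictors,
n = 1000), five strategies fitted and scored against the truth:

```python
import numpy as np
from coxbench.experiment import ExperimentConfig, build_context, run_replicate

cfg = ExperimentConfig(scenario=1, n=1000, epv_levels=(2.5,), replicates=1,
                       master_seed=42,
                       methods=("full", "be_0.05", "ridge", "lasso", "elastic"))
ctx = build_context(cfg)
print(f"censoring horizon delta = {ctx.deltas[2.5]:.3f} y "
      f"(target 22.5 events = EPV 2.5 x 9 candidates)")
rows = run_replicate(ctx, 2.5, 0)
print(f"observed events: {rows[0]['n_events']}")
print(f"{'method':>8}  {'RMSE':>7}  {'slope':>6}  {'conc':>6}")
for r in rows:
    s = "    NA" if not np.isfinite(r['slope']) else f"{r['slope']:6.2f}"
    c = "    NA" if not np.isfinite(r['concordance']) else f"{r['concordance']:6.3f}"
    print(f"{r['method']:>8}  {r['rmse_mean']:7.4f}  {s}  {c}")
```

which prints:

```
censoring horizon delta = 0.632 y (target 22.5 events = EPV 2.5 x 9 candidates)
observed events: 28
  method     RMSE   slope    conc
    full   0.0071    0.05   0.801
 be_0.05   0.0078      NA      NA
   ridge   0.0060    1.12   0.796
   lasso   0.0057    0.86   0.803
 elastic   0.0057    0.86   0.803
```

Reading it: the censoring horizon δ was solved so 22.5 events are expected
(28 realized here).  At this EPV the full model is drastically overfit — a
calibration slope of 0.05 means its predicted risks are spread ~20× too
wide — while ridge slightly over-shrinks (slope 1.12) and the penalized
methods have the lowest RMSE.  Backward elimination at α = 0.05 discarded
every predictor, so it predicts one common survival curve: its slope and
concordance are undefined (NA) and only its RMSE is scored.  Replicated
over hundreds of datasets (`run_experiment`), these per-replicate records
aggregate into mean / trimmed-mean / median summaries with
usable-replicate accounting per method and EPV level.

## Command line

```bash
coxbench simulate --scenario 1 --epv 2.5 --n 1000 --seed 3 --outdir out/   # one dataset + truth
coxbench fit out/dataset.csv --method ridge --method be_0.05 --outdir out/ # fit a CSV survival table
coxbench evaluate truth.csv predicted.csv                                  # metrics from matrices
coxbench run --scenario 1 --epv 2.5 --epv 10 --replicates 100 --seed 7 --outdir out/
```

`coxbench run` writes `records.csv` (one row per replicate × method),
`summary.csv`, a usable-counts table (`table1.csv`), degeneracy fractions
and the resolved `config.yaml`; a YAML config can drive the whole run via
`--config`.

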