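# peskit — unbiased post-error slowing for interference tasks

After committing an error, people slow down: reaction times (RTs) on correct
trials that follow an error are longer than on other correct trials.  This
**post-error slowing (PES)** is a standard index of performance monitoring
and is widely used in clinical and developmental work, which makes unbiased
estimation matter.

Two estimators are in common use.  The *traditional* estimator compares
post-error trials to post-correct trials; the *robust* estimator compares
post-error trials to *pre-error* trials (correct trials that immediately
precede an error), which immunises the contrast against slow drifts in speed
or accuracy over the session.  In **interference tasks** (flanker, Stroop),
however, both can still be biased: conditions differ in speed and accuracy
(congruent trials are fast and easy, incongruent trials slow and error-prone),
and the congruent/incongruent composition of post-correct, pre-error and
post-error trials deviates from the designed 50/50 — errors follow congruent
trials more often (conflict adaptation), and incongruent post-error trials
are more often themselves errors and hence excluded.  Pooling conditions
before averaging then yields a count-weighted mixture mean.  For cell mean
RTs the bias is exactly

```
RT_bias = (RT̄_incon − RT̄_con) / 100 × (deviation from 50%, in percentage points)
```

so a 100-ms interference effect with a 70%/30% split biases the cell by
20 ms; for medians the bias is non-linear and at least as large.  The fix is
to compute **unweighted means**: average congruent and incongruent RTs
separately, then average the two condition values, per trial type and per
response–stimulus interval (RSI) stratum.

`peskit` implements the full pipeline:

* **`peskit.datamodel`** — tidy CSV/TSV trial logs, validated round-trip I/O;
* **`peskit.classify`** — sequence-role classification (error, post-correct,
  pre-error, post-error, with the error–correct–error ambiguity exclusion)
  and trial filters (post-break, 100–1500 ms RT range, MAD outlier screen);
* **`peskit.estimate`** — the four estimators (traditional/robust ×
  pooled/unweighted) in mean- and median-based forms, RSI-stratified;
  imbalance diagnostics, constraint-relaxation tables, participant screening,
  group aggregation with Cohen's d_Z and multilevel bootstrap CIs;
* **`peskit.bias`** — the analytic mean-bias formula and a numerical
  mixture-median bias model (root search on the mixture CDF), plus bias
  grids over interference × imbalance × SD;
* **`peskit.simulate`** — a seeded synthetic flanker-task generator (1088
  trials, breaks every 200, counterbalanced transitions, RSIs of 250/700 ms,
  conflict-adaptive error rates, injected slowing, drift confounds) so every
  stage is testable without archived study data;
* **`peskit.cli`** — `peskit simulate | classify | estimate | bias-grid |
  report`.

## Worked example

```sh
$ peskit simulate --preset paper_like --n 20 --seed 42 --out trials.csv
wrote 20 participants to trials.csv
$ peskit report --input trials.csv
participants included: 20 / 20

Group PES (ms):
     method  correction central   rsi  n  pes_mean_ms  pes_sd_ms  ...
     robust   corrected    mean  long 20         48.6       13.6  ...
     robust   corrected    mean short 20         42.7       15.5  ...
     robust uncorrected    mean  long 20         54.6       12.7  ...
     robust uncorrected    mean short 20         48.9       13.3  ...
...

Uncorrected-vs-corrected bias (ms):
     method central   rsi  n  bias_mean_ms  bias_sd_ms  d_z  percent_inflation
     robust    mean  long 20          6.01        5.92 1.02              12.36
     robust    mean short 20          6.14        6.59 0.93              14.36
traditional    mean  long 20          1.72        5.07 0.34               3.62
traditional    mean short 20          2.80        4.37 0.64               6.72
```

The preset injects a 50-ms slowing; the corrected robust estimates recover it
(48.6 / 42.7 ms, within sampling noise at n = 20), while the pooled
("uncorrected") estimates run ~6 ms high — exactly the direction the
congruent surplus among pre-error trials predicts, and larger for the robust
estimator because its pre-error baseline is the more imbalanced trial type.

The same computation in Python:

```python
from peskit import (Central, Correction, Method, Rsi, apply_filters,
                    cell_statistics, classify_trials, pes_estimate,
                    SimulationConfig, simulate_participant)

ds = simulate_participant(SimulationConfig(seed=3), "p1")
labels = apply_filters(ds, classify_trials(ds))
cells = cell_statistics(ds, labels, Central.MEAN)
est = pes_estimate(cells, method=Method.ROBUST,
                   correction=Correction.CORRECTED, rsi=Rsi.LONG)
print(round(est.pes_ms, 1))   # 24.6 — one participant, noisy by itself
```

## Documentation

See `docs/methods.md` for the statistical model, the generator's assumptions,
numerical choices and known limitations.
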