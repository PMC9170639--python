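# Methods

## Estimands and estimators

For each participant, trials are classified by their accuracy context:
*error* (incorrect response), *post-correct* (correct, preceded by a correct
trial), *pre-error* (correct, preceded by a correct trial, followed by an
error; every pre-error trial is also post-correct), and *post-error*
(correct, preceded by an error, followed by a correct trial).  A single
correct trial flanked by two errors is simultaneously post-error and
pre-error; it is flagged *ambiguous* and excluded.  Trials adjacent to a
no-response trial receive no role that depends on that neighbour, because
the neighbour's accuracy context is undefined — the conservative reading of
omitting non-responses from analysis.

Post-error slowing is a difference of trial-type RT summaries, stratified by
the response–stimulus interval (RSI) class *preceding* each trial (PES
depends strongly on RSI, so baseline and post-error cells are always matched
on it):

| estimator | baseline | congruency handling |
|---|---|---|
| traditional, pooled | post-correct | concatenate conditions, then average |
| traditional, unweighted | post-correct | average conditions separately, then average the two values |
| robust, pooled | pre-error | concatenate |
| robust, unweighted | pre-error | average separately |

Each is available with cell means or cell medians (even-sized medians use
midpoint interpolation, which is what makes the canonical 20-trial example's
pooled post-error median 1200 ms).  The robust baseline protects against
slow performance drifts; the unweighted ("corrected") averaging protects
against congruency imbalance.  Only the combination is drift- and
imbalance-robust.

## The imbalance bias

Pooling congruency conditions averages a two-component mixture with weights
equal to the (imbalanced) trial counts.  For means the exact identity

    pooled − unweighted = (p_con − ½)(mean_con − mean_incon)

holds per cell, so the cell-level bias is linear in the interference effect
I = mean(incon) − mean(con) and the imbalance, and independent of the
component SD.  `mean_bias(I, p_con)` returns I/100 × (percentage-point
deviation from 50), i.e. the amount by which the unweighted cell value
exceeds the pooled one when congruent (fast) trials are over-represented.
PES-level bias composes with opposite signs on the two cells:

    bias(PES) = cell_bias(post_error) − cell_bias(baseline)

which the estimators reproduce exactly (`pes_bias` = pooled PES − unweighted
PES); a congruent surplus concentrated in the *baseline* inflates PES.

For medians there is no closed form.  `mixture_central` solves
w·Φ((m−μ_con)/σ) + (1−w)·Φ((m−μ_incon)/σ) = ½ for m by bracketed root
search (Brent, bracket [min(μ)−10σ, max(μ)+10σ], tolerance 0.01 ms; the
mixture CDF is strictly increasing so the root is unique).  At σ = 0 the CDF
is a two-step function and the median equals the majority component's mean
(midpoint at w = ½) — the limit in which even a one-trial imbalance shifts
the pooled median entirely onto the larger component.  The median bias always
has the same sign as the mean bias and at least its magnitude, grows
non-linearly with interference, and increases as σ shrinks; as σ → ∞ it
approaches the mean bias.  These properties are verified against a direct
sampling oracle (10⁶ mixture draws) in the test suite.

## Filters and screening

Defaults follow standard practice for speeded interference tasks: drop
trials immediately following a break, drop RTs outside [100, 1500] ms, then
flag MAD outliers among the surviving correct RTs per participant ×
congruency × preceding-RSI cell (scale 1.4826, threshold 2.5).  Grouping by
condition rather than the whole session avoids flagging slow-condition
trials against fast-condition medians and is configurable because published
practice varies.  A cell with zero MAD (identical RTs) flags nothing.
Filter order (break/range before MAD) matters only through the MAD pool and
is fixed for determinism.  Roles are never recomputed after filtering: a
filtered trial keeps its accuracy status for its neighbours' roles and only
loses its own RT from averaging — recomputing adjacency across gaps would
fabricate neighbour pairs the participant never experienced.

Participant screening requires ≥ 5 eligible trials in each of the eight
pre-error/post-error × congruency × RSI cells (post-correct cells are only
required non-empty — they are plentiful by construction), ≥ 80% accuracy on
congruent and ≥ 60% on incongruent trials, and, as optional sanity flags
(default on), a positive interference effect and a higher incongruent than
congruent error rate.  Accuracy is computed after break/range removal but
before MAD removal, since the MAD screen targets RT distributions, not
accuracy; no-response trials never enter accuracy denominators.  All
boundaries are inclusive.

Median-based analyses skip the MAD screen (the median is insensitive to the
outliers it targets), which is why median-based runs can retain more
participants than mean-based runs on the same data.

**Known interaction.** MAD screening within condition cells pools post-error
RTs with the unslowed majority of the cell.  When post-error slowing is
genuinely present, the slowed trials sit high in the pooled distribution and
their upper tail is trimmed asymmetrically, attenuating the recovered
effect (≈ −5 ms for a 50-ms effect at σ = 70 ms with the default threshold,
by truncated-normal arithmetic; the test suite asserts the direction).  The
package therefore runs its parameter-recovery validations with break/range
filters only, and users estimating absolute PES magnitudes should be aware
that MAD screening biases them toward zero.

## Group statistics

Per-participant estimates are averaged per method × correction × central ×
RSI; dispersions are across-participant SDs of the per-participant values
(and are labelled as such).  The pooling bias is summarised per participant
as uncorrected − corrected PES; the paired effect size is Cohen's
d_Z = mean(bias)/SD(bias), reported as undefined (NaN) when the SD is zero;
percent inflation is 100 × mean(bias) / mean(corrected PES).  Confidence
intervals use a two-level percentile bootstrap (default 1000 iterations,
95%): each replicate resamples participants with replacement, then
observations within each sampled participant, matching the repeated-measures
structure; with one observation per participant this reduces to a
participant-level bootstrap.

`expected_post_correct_counts` reproduces the design arithmetic for a 50/50
session: with E errors, the E error trials, the E expected post-error trials
and the first trial are unavailable, and each congruency loses its own
errors plus E/2 expected post-error trials.  Returned values are
expectations and may be fractional for odd E.

## Synthetic task generator

The generator emulates a speeded arrow-flanker session: 1088 trials with
breaks every 200; 50% congruent with counterbalanced congruency transitions
(the four transition types occur equally often up to ±1, implemented as a
seeded feasible walk over the transition multigraph, giving exactly 544
congruent trials); preceding-RSI classes short/long balanced within
congruency; the first trial has no preceding RSI and is never
measurement-eligible.

Accuracy: base error rates 5.0% (congruent) and 29.9% (incongruent) —
typical of speeded flanker performance — with conflict adaptation as an
additive shift of ± increment/2 depending on previous-trial congruency
(default increment 0.037, i.e. a 3.7-percentage-point gap between error
rates after congruent vs after incongruent trials; centring keeps the
marginal rates at their base values).  This error-rate channel alone
produces the congruent surplus among pre-error trials; the post-error
surplus emerges from selecting *correct* post-error trials without any
additional mechanism, and post-error accuracy is deliberately left
unchanged.  RT-level congruency-sequence effects are not modelled.

RTs: per congruency × RSI normal components.  Defaults place short-RSI
trials slower than long-RSI trials (less preparation time under a response
deadline) with interference effects of 60 ms (short) and 90 ms (long) and a
common within-cell SD of 70 ms — values chosen once as representative of a
speeded deadline task with mean RTs in the 340–480 ms range; the RSI-
increasing interference makes the long-RSI pooling bias the larger one.  An
ex-Gaussian option (additive exponential tail) is available for studying
median-vs-mean differences under realistic skew; the default stays normal to
match the assumptions of the analytic bias model.  Post-error slowing is
injected additively (default 50 ms, per-congruency configurable) on every
trial following an error.  Because simulated RT and accuracy are
conditionally independent given the design, selecting correct post-error
trials does not distort their RT distribution, so the unweighted robust
estimator recovers the injected slowing without systematic bias — the basis
of the parameter-recovery validation (200 participants, recovery within
±3 ms).

Drifts enter additively on the RT mean and on the error log-odds, centred so
session-average rates are preserved: *linear* (fatigue — slowing plus rising
error rate concentrates errors late in slow phases, spuriously inflating the
traditional pooled estimator) and *phase* (response caution — a careful
slow/accurate first half and a sloppy fast/error-prone second half,
spuriously deflating it).  The presets `fatigue_confound` and
`caution_confound` use total deltas of 80 ms and 1.5 log-odds units, large
enough to make the confound direction unambiguous at 200 participants while
keeping error rates in a plausible range; `paper_like`, `null_pes` and
`strong_adaptation` cover the reference condition, the no-slowing null, and
a doubled adaptation gap.

What the generator does *not* emulate: sequential RT autocorrelation beyond
the injected post-error effect, speed–accuracy trade-offs within a trial
(accuracy is independent of the drawn RT), RT-level conflict adaptation,
stimulus-level effects (flanker–target distance is carried in the data model
but generated as a single level), and post-error accuracy changes.  Passing
the recovery tests therefore shows the estimators are unbiased under the
mixture-and-drift mechanisms they are designed for, not that they are
unbiased under every empirical RT process.

## Numerical and design choices

* Worked-example logs embed each listed pre-error/post-error pair in a
  `correct, pre-error, error, post-error, correct` quintuple so that
  classification recovers exactly the listed trials; such two-value cells
  are a degenerate input for the MAD screen (it would flag the minority
  value), so the reference computations run with break/range filters only.
* The constraint-relaxation diagnostic defines the pre-error candidate as
  the trial immediately before each error and evaluates the four constraint
  modes literally; a candidate whose required error−2 trial does not exist
  fails that constraint.  Candidates without a preceding RSI (session-first
  trials) cannot be stratified and are skipped.
* Trial logs are plain UTF-8 CSV/TSV with fixed snake-case headers; RSI is
  stored as a class label, with optional numeric-ms input binned at a
  user-supplied threshold (the analysis concerns two discrete RSI classes).
  `first_after_break` is this package's convention for encoding breaks,
  stored as 0/1.
* Per-study simulation spawns child seeds via `numpy` `SeedSequence`, so
  studies are reproducible and participants independent; all child seeds
  stay below 2³¹.
* Exit codes: 0 success, 1 usage error, 2 data error.  Result tables are
  tidy (one estimate per row).

## Validation problem sizes

The automated checks use: 1000 random accuracy sequences of length 200
against a brute-force triple-scan enumerator (exact agreement); 20 random
mixture specs against 10⁶-draw Monte-Carlo medians (±1 ms); 200 simulated
participants for parameter recovery (±3 ms on a 50-ms effect) and for each
confound-direction check; and 200 replicates of 15 × 20 two-level normal
data for bootstrap coverage.  These sizes keep Monte-Carlo error well below
the asserted tolerances.
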