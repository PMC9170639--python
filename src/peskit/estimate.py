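"""Post-error slowing (PES) estimators and congruency-imbalance diagnostics.

Four PES estimators are supported, crossing the choice of baseline with the
choice of congruency handling, each available with mean- or median-based cell
central tendencies and stratified by the RSI class preceding each trial:

* traditional, uncorrected:  PES = RT(post-error) - RT(post-correct), both
  pooled over congruency (weighted by trial counts).
* traditional, corrected:    as above, but each trial type's RT is the
  unweighted average of its congruent and incongruent cell values.
* robust, uncorrected:       PES = RT(post-error) - RT(pre-error), pooled.
* robust, corrected:         unweighted congruency averages of post-error and
  pre-error RTs.

The pooled (uncorrected) variants are biased whenever the congruent fraction
of a trial type deviates from the design's 50%, because congruent trials are
systematically faster: the pooled mean is a count-weighted mixture of the two
condition means.  The corrected variants remove that bias by construction.
For mean-based cells the exact identity

    pooled - unweighted = (p_con - 1/2) * (mean_con - mean_incon)

links the two, where ``p_con`` is the cell's congruent proportion.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import ExclusionReason, Role, TrialLabel
from .datamodel import Accuracy, Congruency, ParticipantDataset, Rsi

__all__ = [
    "Central",
    "Method",
    "Correction",
    "CellStatistic",
    "PESEstimate",
    "ImbalanceSummary",
    "InclusionReport",
    "ScreeningCriteria",
    "RelaxationMode",
    "EstimationError",
    "cell_statistics",
    "pes_estimate",
    "pes_bias",
    "imbalance_summary",
    "constraint_relaxation_imbalance",
    "screen_participant",
    "participant_estimates",
    "group_aggregate",
    "multilevel_bootstrap_ci",
    "expected_post_correct_counts",
]


class Central(str, enum.Enum):
    MEAN = "mean"
    MEDIAN = "median"


class Method(str, enum.Enum):
    TRADITIONAL = "traditional"
    ROBUST = "robust"


class Correction(str, enum.Enum):
    UNCORRECTED = "uncorrected"
    CORRECTED = "corrected"


#: Trial types that contribute RT cells to PES estimation.
MEASUREMENT_ROLES = (Role.POST_CORRECT, Role.PRE_ERROR, Role.POST_ERROR)

_BASELINE_ROLE = {Method.TRADITIONAL: Role.POST_CORRECT, Method.ROBUST: Role.PRE_ERROR}


class EstimationError(ValueError):
    """A required RT cell is empty or estimator inputs are inconsistent."""


@dataclass(frozen=True)
class CellStatistic:
    """Central tendency of one trial-type cell.

    ``congruency=None`` denotes the pooled cell (congruent and incongruent
    RTs concatenated before averaging).
    """

    trial_type: Role
    rsi: Rsi
    congruency: Congruency | None
    central: Central
    value_ms: float
    n_trials: int
    sd_ms: float | None = None


@dataclass(frozen=True)
class PESEstimate:
    participant_id: str
    method: Method
    correction: Correction
    central: Central
    rsi: Rsi
    baseline_ms: float
    post_error_ms: float

    @property
    def pes_ms(self) -> float:
        return self.post_error_ms - self.baseline_ms


@dataclass(frozen=True)
class ImbalanceSummary:
    """Congruent percentage per (trial type, RSI) stratum.

    ``percent_congruent[(trial_type, rsi)] = 100 * n_con / (n_con + n_incon)``
    over measurement-eligible trials; strata without eligible trials are
    absent.
    """

    percent_congruent: dict[tuple[Role, Rsi], float]
    n_congruent: dict[tuple[Role, Rsi], int]
    n_incongruent: dict[tuple[Role, Rsi], int]


@dataclass(frozen=True)
class ScreeningCriteria:
    min_cell_trials: int = 5
    min_congruent_accuracy: float = 0.80
    min_incongruent_accuracy: float = 0.60
    require_interference_effect: bool = True
    require_error_rate_order: bool = True


@dataclass(frozen=True)
class InclusionReport:
    participant_id: str
    included: bool
    reasons: tuple[str, ...]
    cell_counts: dict[tuple[Role, Congruency, Rsi], int]
    accuracies: dict[Congruency, float]


class RelaxationMode(str, enum.Enum):
    FULL = "full"
    PRE_ERROR_CORRECT_ONLY = "pre_error_correct_only"
    ERROR_MINUS2_CORRECT_ONLY = "error_minus2_correct_only"
    NONE = "none"


def _eligible_rts(dataset: ParticipantDataset, labels: Sequence[TrialLabel],
                  role: Role, rsi: Rsi,
                  congruency: Congruency | None) -> np.ndarray:
    rts = [
        t.rt_ms
        for t, lab in zip(dataset.trials, labels)
        if lab.measurement_eligible
        and role in lab.roles
        and t.preceding_rsi is rsi
        and (congruency is None or t.congruency is congruency)
    ]
    return np.asarray(rts, dtype=float)


def cell_statistics(dataset: ParticipantDataset, labels: Sequence[TrialLabel],
                    central: Central = Central.MEAN) -> list[CellStatistic]:
    """Per-cell central tendencies over measurement-eligible RTs.

    Emits, for every trial type x RSI with at least one eligible trial, the
    two congruency-specific cells and the pooled (concatenated) cell.  Empty
    cells are absent rather than zero.  Medians of even-sized cells use the
    midpoint of the two central order statistics.
    """
    out: list[CellStatistic] = []
    for role in MEASUREMENT_ROLES:
        for rsi in Rsi:
            for cong in (Congruency.CONGRUENT, Congruency.INCONGRUENT, None):
                rts = _eligible_rts(dataset, labels, role, rsi, cong)
                if len(rts) == 0:
                    continue
                value = float(np.mean(rts) if central is Central.MEAN else np.median(rts))
                sd = float(np.std(rts, ddof=1)) if central is Central.MEAN and len(rts) > 1 else None
                out.append(
                    CellStatistic(
                        trial_type=role,
                        rsi=rsi,
                        congruency=cong,
                        central=central,
                        value_ms=value,
                        n_trials=len(rts),
                        sd_ms=sd,
                    )
                )
    return out


def _cell_lookup(cells: Iterable[CellStatistic]):
    return {(c.trial_type, c.rsi, c.congruency, c.central): c for c in cells}


def _trial_type_value(lookup, role: Role, rsi: Rsi, correction: Correction,
                      central: Central) -> float:
    if correction is Correction.UNCORRECTED:
        cell = lookup.get((role, rsi, None, central))
        if cell is None:
            raise EstimationError(f"empty pooled cell: {role.value} x {rsi.value}")
        return cell.value_ms
    values = []
    for cong in (Congruency.CONGRUENT, Congruency.INCONGRUENT):
        cell = lookup.get((role, rsi, cong, central))
        if cell is None:
            raise EstimationError(
                f"empty cell: {role.value} x {cong.value} x {rsi.value}"
            )
        values.append(cell.value_ms)
    return float(np.mean(values))


def pes_estimate(cells: Iterable[CellStatistic], *, participant_id: str = "",
                 method: Method = Method.ROBUST,
                 correction: Correction = Correction.CORRECTED,
                 central: Central = Central.MEAN,
                 rsi: Rsi = Rsi.SHORT) -> PESEstimate:
    """One participant's PES for a (method, correction, central, RSI) combo.

    The baseline trial type is post-correct (traditional) or pre-error
    (robust); baseline and post-error cells always share the same preceding
    RSI class.
    """
    lookup = _cell_lookup(cells)
    baseline = _trial_type_value(lookup, _BASELINE_ROLE[method], rsi, correction, central)
    post_error = _trial_type_value(lookup, Role.POST_ERROR, rsi, correction, central)
    return PESEstimate(
        participant_id=participant_id,
        method=method,
        correction=correction,
        central=central,
        rsi=rsi,
        baseline_ms=baseline,
        post_error_ms=post_error,
    )


def pes_bias(uncorrected: PESEstimate, corrected: PESEstimate) -> float:
    """Signed bias of the uncorrected estimator: uncorrected - corrected (ms).

    Positive values mean pooling over congruency inflated the PES estimate.
    """
    if (
        uncorrected.correction is not Correction.UNCORRECTED
        or corrected.correction is not Correction.CORRECTED
        or uncorrected.participant_id != corrected.participant_id
        or uncorrected.method is not corrected.method
        or uncorrected.central is not corrected.central
        or uncorrected.rsi is not corrected.rsi
    ):
        raise EstimationError("bias requires matched uncorrected/corrected estimates")
    return uncorrected.pes_ms - corrected.pes_ms


def imbalance_summary(dataset: ParticipantDataset,
                      labels: Sequence[TrialLabel]) -> ImbalanceSummary:
    """Percent congruent among eligible trials of each trial type x RSI."""
    pct: dict[tuple[Role, Rsi], float] = {}
    n_con: dict[tuple[Role, Rsi], int] = {}
    n_incon: dict[tuple[Role, Rsi], int] = {}
    for role in MEASUREMENT_ROLES:
        for rsi in Rsi:
            counts = {Congruency.CONGRUENT: 0, Congruency.INCONGRUENT: 0}
            for t, lab in zip(dataset.trials, labels):
                if lab.measurement_eligible and role in lab.roles and t.preceding_rsi is rsi:
                    counts[t.congruency] += 1
            total = sum(counts.values())
            if total == 0:
                continue
            key = (role, rsi)
            n_con[key] = counts[Congruency.CONGRUENT]
            n_incon[key] = counts[Congruency.INCONGRUENT]
            pct[key] = 100.0 * n_con[key] / total
    return ImbalanceSummary(percent_congruent=pct, n_congruent=n_con, n_incongruent=n_incon)


def constraint_relaxation_imbalance(dataset: ParticipantDataset,
                                    mode: RelaxationMode = RelaxationMode.FULL
                                    ) -> dict[Rsi, float]:
    """Percent congruent pre-error trials under relaxed definitions.

    The candidate pre-error trial for an error at position ``i`` is the trial
    at ``i-1``; ``error-2`` is the trial at ``i-2``.  Modes:

    * ``full``: pre-error and error-2 trial both correct (the analysis
      definition).
    * ``pre_error_correct_only``: pre-error correct, error-2 unconstrained.
    * ``error_minus2_correct_only``: error-2 correct, pre-error
      unconstrained.
    * ``none``: any trial preceding an error.

    Returns percent congruent per preceding-RSI class of the candidate trial;
    strata with no qualifying trials (including error-free datasets) are
    absent.
    """
    trials = dataset.trials
    counts: dict[Rsi, list[int]] = {rsi: [0, 0] for rsi in Rsi}
    for i, t in enumerate(trials):
        if t.accuracy is not Accuracy.ERROR or i == 0:
            continue
        cand = trials[i - 1]
        if cand.preceding_rsi is None:
            continue
        pre_ok = cand.accuracy is Accuracy.CORRECT
        em2_ok = i >= 2 and trials[i - 2].accuracy is Accuracy.CORRECT
        if mode is RelaxationMode.FULL and not (pre_ok and em2_ok):
            continue
        if mode is RelaxationMode.PRE_ERROR_CORRECT_ONLY and not pre_ok:
            continue
        if mode is RelaxationMode.ERROR_MINUS2_CORRECT_ONLY and not em2_ok:
            continue
        counts[cand.preceding_rsi][0 if cand.congruency is Congruency.CONGRUENT else 1] += 1
    return {
        rsi: 100.0 * c / (c + ic)
        for rsi, (c, ic) in counts.items()
        if c + ic > 0
    }


def screen_participant(dataset: ParticipantDataset, labels: Sequence[TrialLabel],
                       criteria: ScreeningCriteria = ScreeningCriteria()
                       ) -> InclusionReport:
    """Decide whether a participant enters the PES analysis.

    Requirements: at least ``min_cell_trials`` eligible trials in every
    pre-error/post-error x congruency x RSI cell; accuracy of at least 80% on
    congruent and 60% on incongruent trials; and (optional sanity flags) a
    positive interference effect on correct trials and a higher error rate on
    incongruent than congruent trials.  Accuracy and error rates are computed
    after post-break/RT-range removal but before MAD screening, since the MAD
    screen targets correct-RT distributions, not accuracy; no-response trials
    never enter accuracy denominators.
    """
    reasons: list[str] = []
    cell_counts: dict[tuple[Role, Congruency, Rsi], int] = {}
    for role in (Role.PRE_ERROR, Role.POST_ERROR):
        for cong in Congruency:
            for rsi in Rsi:
                n = sum(
                    1
                    for t, lab in zip(dataset.trials, labels)
                    if lab.measurement_eligible
                    and role in lab.roles
                    and t.congruency is cong
                    and t.preceding_rsi is rsi
                )
                cell_counts[(role, cong, rsi)] = n
    if any(n < criteria.min_cell_trials for n in cell_counts.values()):
        reasons.append("too_few_cell_trials")

    # Accuracy pool: responded trials, not post-break, RT in range.
    pool = [
        (t, lab)
        for t, lab in zip(dataset.trials, labels)
        if t.accuracy is not Accuracy.NO_RESPONSE
        and lab.exclusion_reason
        not in (ExclusionReason.POST_BREAK, ExclusionReason.RT_OUT_OF_RANGE)
    ]
    accuracies: dict[Congruency, float] = {}
    err_rate: dict[Congruency, float] = {}
    rt_correct: dict[Congruency, list[float]] = {c: [] for c in Congruency}
    for cong in Congruency:
        sub = [t for t, _ in pool if t.congruency is cong]
        n_corr = sum(1 for t in sub if t.accuracy is Accuracy.CORRECT)
        if sub:
            accuracies[cong] = n_corr / len(sub)
            err_rate[cong] = 1 - accuracies[cong]
        rt_correct[cong] = [t.rt_ms for t in sub if t.accuracy is Accuracy.CORRECT]
    if accuracies.get(Congruency.CONGRUENT, 0.0) < criteria.min_congruent_accuracy:
        reasons.append("low_congruent_accuracy")
    if accuracies.get(Congruency.INCONGRUENT, 0.0) < criteria.min_incongruent_accuracy:
        reasons.append("low_incongruent_accuracy")
    if criteria.require_interference_effect:
        if not (
            rt_correct[Congruency.CONGRUENT]
            and rt_correct[Congruency.INCONGRUENT]
            and np.mean(rt_correct[Congruency.INCONGRUENT])
            > np.mean(rt_correct[Congruency.CONGRUENT])
        ):
            reasons.append("no_interference_effect")
    if criteria.require_error_rate_order:
        if not (
            Congruency.CONGRUENT in err_rate
            and Congruency.INCONGRUENT in err_rate
            and err_rate[Congruency.INCONGRUENT] > err_rate[Congruency.CONGRUENT]
        ):
            reasons.append("inverted_error_rates")

    return InclusionReport(
        participant_id=dataset.participant_id,
        included=not reasons,
        reasons=tuple(reasons),
        cell_counts=cell_counts,
        accuracies=accuracies,
    )


def participant_estimates(dataset: ParticipantDataset, labels: Sequence[TrialLabel],
                          centrals: Sequence[Central] = (Central.MEAN,),
                          ) -> list[PESEstimate]:
    """All method x correction x central x RSI estimates for one participant.

    Combinations whose required cells are empty are silently omitted; callers
    that need strict behaviour use :func:`pes_estimate` directly.
    """
    out: list[PESEstimate] = []
    for central in centrals:
        cells = cell_statistics(dataset, labels, central)
        for method in Method:
            for correction in Correction:
                for rsi in Rsi:
                    try:
                        out.append(
                            pes_estimate(
                                cells,
                                participant_id=dataset.participant_id,
                                method=method,
                                correction=correction,
                                central=central,
                                rsi=rsi,
                            )
                        )
                    except EstimationError:
                        continue
    return out


def estimates_to_frame(estimates: Iterable[PESEstimate]) -> pd.DataFrame:
    rows = [
        {
            "participant_id": e.participant_id,
            "method": e.method.value,
            "correction": e.correction.value,
            "central": e.central.value,
            "rsi": e.rsi.value,
            "baseline_ms": e.baseline_ms,
            "post_error_ms": e.post_error_ms,
            "pes_ms": e.pes_ms,
        }
        for e in estimates
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "method", "correction", "central", "rsi",
            "baseline_ms", "post_error_ms", "pes_ms",
        ],
    )


def group_aggregate(estimates: Iterable[PESEstimate]) -> dict[str, pd.DataFrame]:
    """Group-level summary of PES estimates and uncorrected-vs-corrected bias.

    Returns two tidy tables:

    * ``"pes"`` -- mean and across-participant SD of PES (and of its baseline
      and post-error components) per method x correction x central x RSI.
    * ``"bias"`` -- per method x central x RSI: mean and SD of the
      within-participant bias (uncorrected - corrected), the paired effect
      size ``d_z = mean(bias)/SD(bias)`` (NaN when the SD is zero), and the
      percent inflation ``100 * mean(bias) / mean(corrected PES)``.
    """
    df = estimates_to_frame(estimates)
    if df.empty:
        raise EstimationError("no estimates to aggregate")
    keys = ["method", "correction", "central", "rsi"]
    pes = (
        df.groupby(keys, sort=True)
        .agg(
            n=("participant_id", "nunique"),
            pes_mean_ms=("pes_ms", "mean"),
            pes_sd_ms=("pes_ms", "std"),
            baseline_mean_ms=("baseline_ms", "mean"),
            baseline_sd_ms=("baseline_ms", "std"),
            post_error_mean_ms=("post_error_ms", "mean"),
            post_error_sd_ms=("post_error_ms", "std"),
        )
        .reset_index()
    )

    wide = df.pivot_table(
        index=["participant_id", "method", "central", "rsi"],
        columns="correction",
        values="pes_ms",
    ).dropna()
    bias_rows = []
    if not wide.empty:
        wide = wide.reset_index()
        wide["bias_ms"] = wide["uncorrected"] - wide["corrected"]
        for (method, central, rsi), grp in wide.groupby(["method", "central", "rsi"], sort=True):
            mean_bias = float(grp["bias_ms"].mean())
            sd_bias = float(grp["bias_ms"].std(ddof=1)) if len(grp) > 1 else np.nan
            d_z = mean_bias / sd_bias if sd_bias and sd_bias > 0 else np.nan
            mean_corr = float(grp["corrected"].mean())
            inflation = 100.0 * mean_bias / mean_corr if mean_corr != 0 else np.nan
            bias_rows.append(
                {
                    "method": method,
                    "central": central,
                    "rsi": rsi,
                    "n": len(grp),
                    "bias_mean_ms": mean_bias,
                    "bias_sd_ms": sd_bias,
                    "d_z": d_z,
                    "percent_inflation": inflation,
                }
            )
    bias = pd.DataFrame(
        bias_rows,
        columns=[
            "method", "central", "rsi", "n",
            "bias_mean_ms", "bias_sd_ms", "d_z", "percent_inflation",
        ],
    )
    return {"pes": pes, "bias": bias}


def multilevel_bootstrap_ci(data: Sequence[Sequence[float]],
                            statistic: Callable[[np.ndarray], float] = np.mean,
                            n_iter: int = 1000, level: float = 0.95,
                            seed: int | np.random.Generator | None = None
                            ) -> tuple[float, float]:
    """Two-level percentile bootstrap interval for repeated-measures data.

    Each replicate first resamples participants with replacement, then
    resamples observations within each sampled participant with replacement,
    and applies ``statistic`` to the concatenated observations.  With a single
    participant this reduces to an ordinary bootstrap of that participant's
    observations.
    """
    arrays = [np.asarray(p, dtype=float) for p in data]
    if not arrays or any(len(a) == 0 for a in arrays):
        raise ValueError("every participant must contribute at least one observation")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_p = len(arrays)
    reps = np.empty(n_iter)
    for b in range(n_iter):
        chosen = rng.integers(0, n_p, size=n_p)
        pooled = np.concatenate(
            [arrays[i][rng.integers(0, len(arrays[i]), size=len(arrays[i]))] for i in chosen]
        )
        reps[b] = statistic(pooled)
    alpha = (1 - level) / 2
    return (
        float(np.quantile(reps, alpha)),
        float(np.quantile(reps, 1 - alpha)),
    )


def expected_post_correct_counts(n_trials: int, n_con_errors: int, n_incon_errors: int
                                 ) -> tuple[float, float, float]:
    """Expected post-correct trial counts in a 50/50 design with given errors.

    With ``E = n_con_errors + n_incon_errors`` errors, the error trials, the
    (expected) ``E`` post-error trials and the first trial are unavailable as
    post-correct trials, leaving ``n_trials - 2E - 1`` in total.  Post-error
    trials are assumed to split evenly by congruency (trial order is random),
    so each congruency contributes half the trials of that congruency minus
    its own errors minus ``E/2`` expected post-error trials.

    Returns ``(total, n_congruent, n_incongruent)``; entries may be
    fractional when ``E`` is odd (they are expectations, not realisations).
    """
    errors = n_con_errors + n_incon_errors
    total = n_trials - 2 * errors - 1
    per_condition = n_trials // 2
    n_con = per_condition - n_con_errors - errors / 2
    n_incon = per_condition - n_incon_errors - errors / 2
    if total < 0 or n_con < 0 or n_incon < 0:
        raise ValueError("error counts imply negative post-correct cells")
    return (float(total), float(n_con), float(n_incon))
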