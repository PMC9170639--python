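"""Sequence-role classification and trial-level filtering.

Post-error slowing analyses assign each trial a role from its local accuracy
context:

* ``error`` -- an incorrect response.
* ``post_correct`` -- a correct trial following a correct trial (the baseline
  of the traditional estimator).
* ``pre_error`` -- a correct trial that follows a correct trial AND precedes
  an error (the baseline of the robust estimator; every pre-error trial is
  also a post-correct trial).
* ``post_error`` -- a correct trial that follows an error and precedes a
  correct trial.

A single correct trial between two errors is both post-error and pre-error at
once; such trials are *ambiguous* and receive no role.  Trials adjacent to a
no-response trial receive no role that depends on that neighbour, because the
neighbour's accuracy context is undefined.

Role assignment is a pure function of the accuracy sequence; reaction times
only enter through the filters (:func:`apply_filters`), which decide whether a
trial's RT may be averaged but never rewrite roles: a filtered trial's
accuracy still informs its neighbours' roles, so no artificial adjacency is
created.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

from .datamodel import Accuracy, ParticipantDataset

__all__ = [
    "Role",
    "ExclusionReason",
    "TrialLabel",
    "FilterConfig",
    "MadGrouping",
    "classify_trials",
    "apply_filters",
]


class Role(str, enum.Enum):
    ERROR = "error"
    POST_CORRECT = "post_correct"
    PRE_ERROR = "pre_error"
    POST_ERROR = "post_error"


class ExclusionReason(str, enum.Enum):
    NONE = "none"
    POST_BREAK = "post_break"
    RT_OUT_OF_RANGE = "rt_out_of_range"
    MAD_OUTLIER = "mad_outlier"
    NO_RESPONSE_CONTEXT = "no_response_context"
    AMBIGUOUS_BETWEEN_ERRORS = "ambiguous_between_errors"


class MadGrouping(str, enum.Enum):
    PARTICIPANT = "participant"
    PARTICIPANT_BY_CONDITION = "participant_by_condition"


@dataclass(frozen=True)
class TrialLabel:
    """Derived sequence role(s) and measurement eligibility of one trial."""

    trial_index: int
    roles: frozenset[Role] = frozenset()
    ambiguous: bool = False
    measurement_eligible: bool = False
    exclusion_reason: ExclusionReason = ExclusionReason.NONE


@dataclass(frozen=True)
class FilterConfig:
    """Trial-level RT filters.

    ``rt_min_ms``/``rt_max_ms`` bound plausible reaction times (default
    100--1500 ms).  MAD outlier rejection flags an RT ``x`` within its group
    when ``|x - median| / (mad_scale * median(|x - median|)) > mad_threshold``;
    the default scale 1.4826 makes the scaled MAD a consistent SD estimator
    under normality and the default threshold is 2.5.  ``use_mad=False``
    disables the screen (appropriate for median-based estimation, which is
    insensitive to outliers).
    """

    rt_min_ms: float = 100.0
    rt_max_ms: float = 1500.0
    mad_scale: float = 1.4826
    mad_threshold: float = 2.5
    drop_post_break: bool = True
    use_mad: bool = True
    mad_grouping: MadGrouping = MadGrouping.PARTICIPANT_BY_CONDITION

    def __post_init__(self) -> None:
        if not self.rt_min_ms < self.rt_max_ms:
            raise ValueError("rt_min_ms must be < rt_max_ms")
        if self.mad_threshold <= 0:
            raise ValueError("mad_threshold must be positive")


def classify_trials(dataset: ParticipantDataset) -> list[TrialLabel]:
    """Assign every trial its sequence role(s).

    For trial ``t`` with neighbours ``t-1`` and ``t+1`` (missing at the
    session edges): roles follow the definitions in the module docstring.  A
    role whose defining neighbour is a no-response trial is withheld; if a
    correct trial loses all prospective roles that way it is marked with
    ``no_response_context``.  A correct trial between two errors is flagged
    ambiguous and receives no role.
    """
    acc = [t.accuracy for t in dataset.trials]
    n = len(acc)
    labels: list[TrialLabel] = []
    for i, trial in enumerate(dataset.trials):
        prev = acc[i - 1] if i > 0 else None
        nxt = acc[i + 1] if i < n - 1 else None
        roles: set[Role] = set()
        ambiguous = False
        reason = ExclusionReason.NONE

        if acc[i] is Accuracy.ERROR:
            roles.add(Role.ERROR)
        elif acc[i] is Accuracy.CORRECT:
            if prev is Accuracy.ERROR and nxt is Accuracy.ERROR:
                ambiguous = True
                reason = ExclusionReason.AMBIGUOUS_BETWEEN_ERRORS
            else:
                if prev is Accuracy.CORRECT:
                    roles.add(Role.POST_CORRECT)
                    if nxt is Accuracy.ERROR:
                        roles.add(Role.PRE_ERROR)
                if prev is Accuracy.ERROR and nxt is Accuracy.CORRECT:
                    roles.add(Role.POST_ERROR)
                if not roles and (
                    prev is Accuracy.NO_RESPONSE or nxt is Accuracy.NO_RESPONSE
                ):
                    reason = ExclusionReason.NO_RESPONSE_CONTEXT

        eligible = bool(roles - {Role.ERROR}) and trial.preceding_rsi is not None
        labels.append(
            TrialLabel(
                trial_index=trial.trial_index,
                roles=frozenset(roles),
                ambiguous=ambiguous,
                measurement_eligible=eligible,
                exclusion_reason=reason,
            )
        )
    return labels


def _mad_flags(rts: np.ndarray, scale: float, threshold: float) -> np.ndarray:
    med = np.median(rts)
    mad = np.median(np.abs(rts - med))
    if mad == 0:
        # Degenerate cell (e.g. all values identical): nothing is flagged.
        return np.zeros(len(rts), dtype=bool)
    return np.abs(rts - med) / (scale * mad) > threshold


def apply_filters(dataset: ParticipantDataset, labels: list[TrialLabel],
                  config: FilterConfig = FilterConfig()) -> list[TrialLabel]:
    """Mark post-break, out-of-range and MAD-outlier trials ineligible.

    Filters run in order: post-break removal, RT-range removal, then MAD
    screening computed on the surviving correct RTs of each grouping cell
    (participant, or participant x congruency x preceding-RSI).  Roles are
    never recomputed; a filtered trial keeps its accuracy status for its
    neighbours' roles and only loses its own RT from averaging.
    """
    if len(labels) != len(dataset.trials):
        raise ValueError("labels do not match dataset length")
    out = list(labels)
    trials = dataset.trials

    def demote(i: int, reason: ExclusionReason) -> None:
        if out[i].measurement_eligible:
            out[i] = replace(out[i], measurement_eligible=False, exclusion_reason=reason)

    survives = np.ones(len(trials), dtype=bool)  # enters the MAD pool
    for i, t in enumerate(trials):
        if config.drop_post_break and t.first_after_break:
            demote(i, ExclusionReason.POST_BREAK)
            survives[i] = False
        elif t.rt_ms is not None and not (config.rt_min_ms <= t.rt_ms <= config.rt_max_ms):
            demote(i, ExclusionReason.RT_OUT_OF_RANGE)
            survives[i] = False

    if config.use_mad:
        groups: dict[tuple, list[int]] = {}
        for i, t in enumerate(trials):
            if not survives[i] or t.accuracy is not Accuracy.CORRECT or t.rt_ms is None:
                continue
            if config.mad_grouping is MadGrouping.PARTICIPANT_BY_CONDITION:
                key = (t.congruency, t.preceding_rsi)
            else:
                key = ()
            groups.setdefault(key, []).append(i)
        for idx in groups.values():
            rts = np.array([trials[i].rt_ms for i in idx], dtype=float)
            flags = _mad_flags(rts, config.mad_scale, config.mad_threshold)
            for i, bad in zip(idx, flags):
                if bad:
                    demote(i, ExclusionReason.MAD_OUTLIER)
    return out
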