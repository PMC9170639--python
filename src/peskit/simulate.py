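"""Synthetic speeded flanker-task generator.

Emulates the statistical structure that post-error slowing analyses assume:
a long session (1088 trials by default, with self-paced breaks every 200
trials), 50% congruent trials in pseudo-random order with counterbalanced
congruency transition frequencies, response--stimulus intervals (RSIs) of two
classes (short 250 ms / long 700 ms) balanced within congruency,
congruency-dependent error rates with conflict adaptation (errors are more
likely after congruent trials), condition-dependent RT distributions, an
injected additive post-error slowing, and optional slow drifts in speed and
accuracy that reproduce the classic confounds of the traditional PES
estimator (fatigue inflates it, decreasing response caution deflates it).

All randomness flows through a single integer seed; identical configs and
seeds produce bit-identical datasets.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import Accuracy, Congruency, ParticipantDataset, Rsi, TrialRecord

__all__ = [
    "RtParams",
    "DriftKind",
    "DriftConfig",
    "SimulationConfig",
    "generate_sequence",
    "simulate_participant",
    "simulate_study",
    "scenario_presets",
]

_EPS = 1e-9


@dataclass(frozen=True)
class RtParams:
    """Normal (or ex-Gaussian) RT component for one congruency x RSI cell.

    ``tau_ms > 0`` adds an exponential component of that mean, giving the
    right-skewed ex-Gaussian shape typical of empirical RTs; the cell mean is
    then ``mu_ms + tau_ms``.
    """

    mu_ms: float
    sigma_ms: float
    tau_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_ms <= 0:
            raise ValueError("sigma_ms must be positive")
        if self.tau_ms < 0:
            raise ValueError("tau_ms must be non-negative")


class DriftKind(str, enum.Enum):
    NONE = "none"
    LINEAR = "linear"
    PHASE = "phase"


@dataclass(frozen=True)
class DriftConfig:
    """Slow change in speed and accuracy across the session.

    ``linear``: RT mean and error log-odds change linearly by
    ``rt_delta_ms`` / ``error_logodds_delta`` in total across the session,
    centred so the session-average condition means are unchanged.

    ``phase``: two-phase square wave with period ``2 * phase_length`` trials;
    in the first (high-caution) phase RT is raised by ``rt_delta_ms / 2`` and
    error log-odds lowered by ``error_logodds_delta / 2``, in the second the
    signs flip.  With ``phase_length = n_trials // 2`` this is the
    careful-early / sloppy-late response-caution scenario.
    """

    kind: DriftKind = DriftKind.NONE
    rt_delta_ms: float = 0.0
    error_logodds_delta: float = 0.0
    phase_length: int | None = None


# Default per-condition RT components: short-RSI trials are slower (less
# preparation time) and the interference effect grows with RSI.
_DEFAULT_RT_MODEL = {
    (Congruency.CONGRUENT, Rsi.SHORT): RtParams(mu_ms=420.0, sigma_ms=70.0),
    (Congruency.INCONGRUENT, Rsi.SHORT): RtParams(mu_ms=480.0, sigma_ms=70.0),
    (Congruency.CONGRUENT, Rsi.LONG): RtParams(mu_ms=340.0, sigma_ms=70.0),
    (Congruency.INCONGRUENT, Rsi.LONG): RtParams(mu_ms=430.0, sigma_ms=70.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of one synthetic flanker session.

    Defaults encode the reference task: 1088 trials, breaks every 200, 50%
    congruent with counterbalanced transitions, base error rates 5.0%
    (congruent) / 29.9% (incongruent), a conflict-adaptation gap of 3.7
    percentage points between error rates after congruent vs after
    incongruent trials (applied centred, so marginal error rates stay at the
    base values), and a 50-ms additive post-error slowing in both conditions.
    """

    n_trials: int = 1088
    break_every: int = 200
    p_congruent: float = 0.5
    counterbalance_transitions: bool = True
    rt_model: dict[tuple[Congruency, Rsi], RtParams] = field(
        default_factory=lambda: dict(_DEFAULT_RT_MODEL)
    )
    error_base: dict[Congruency, float] = field(
        default_factory=lambda: {Congruency.CONGRUENT: 0.05, Congruency.INCONGRUENT: 0.299}
    )
    adaptation_increment: float = 0.037
    pes_ms: dict[Congruency, float] = field(
        default_factory=lambda: {Congruency.CONGRUENT: 50.0, Congruency.INCONGRUENT: 50.0}
    )
    no_response_prob: float = 0.0
    drift: DriftConfig = DriftConfig()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")
        if not 0.0 <= self.p_congruent <= 1.0:
            raise ValueError("p_congruent must lie in [0, 1]")
        if not 0.0 <= self.no_response_prob <= 1.0:
            raise ValueError("no_response_prob must lie in [0, 1]")
        for p in self.error_base.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("error probabilities must lie in [0, 1]")
        if self.counterbalance_transitions and self.n_trials < 8:
            raise ValueError("transition counterbalancing needs n_trials >= 8")


def _transition_counts(n_trials: int, rng: np.random.Generator
                       ) -> tuple[bool, dict[str, int]]:
    """Choose first-trial congruency and CC/CI/IC/II transition counts.

    Counts are equal up to +-1, the cross-transition counts differ by at most
    one (so a transition walk exists), and the implied number of congruent
    trials is exactly ``n_trials // 2``.
    """
    m = n_trials - 1
    q = m // 4
    target_c = n_trials // 2
    candidates = []
    for cc in (q, q + 1):
        for ci in (q, q + 1):
            for ic in (q, q + 1):
                ii = m - cc - ci - ic
                if ii not in (q, q + 1) or abs(ci - ic) > 1:
                    continue
                if ci - ic == 1:
                    starts = [True]       # start congruent, end incongruent
                elif ci - ic == -1:
                    starts = [False]
                else:
                    starts = [True, False]
                for first_c in starts:
                    n_c = int(first_c) + cc + ic
                    if n_c == target_c:
                        candidates.append((first_c, {"cc": cc, "ci": ci, "ic": ic, "ii": ii}))
    if not candidates:
        raise ValueError(f"no counterbalanced transition layout for n_trials={n_trials}")
    first_c, counts = candidates[rng.integers(len(candidates))]
    return first_c, counts


def _feasible(counts: dict[str, int], at_congruent: bool) -> bool:
    """Can the remaining transition multiset be walked from the current node?"""
    cc, ci, ic, ii = counts["cc"], counts["ci"], counts["ic"], counts["ii"]
    total = cc + ci + ic + ii
    if total == 0:
        return True
    d = ci - ic
    if ci + ic == 0:
        # Only self-loops remain: they must all sit at the current node.
        return ii == 0 if at_congruent else cc == 0
    if d == 0:
        return True
    return (d == 1 and at_congruent) or (d == -1 and not at_congruent)


def _walk_transitions(first_c: bool, counts: dict[str, int],
                      rng: np.random.Generator) -> np.ndarray:
    """Random transition walk consuming exactly the given counts.

    Boolean congruency sequence; at each step a feasible next transition is
    drawn with probability proportional to its remaining count.
    """
    remaining = dict(counts)
    seq = [first_c]
    at_c = first_c
    total = sum(remaining.values())
    for _ in range(total):
        options = []
        for key, next_c in ((("cc", True) if at_c else ("ic", True)),
                            (("ci", False) if at_c else ("ii", False))):
            if remaining[key] == 0:
                continue
            remaining[key] -= 1
            if _feasible(remaining, next_c):
                options.append((key, next_c, remaining[key] + 1))
            remaining[key] += 1
        weights = np.array([w for _, _, w in options], dtype=float)
        key, next_c, _ = options[rng.choice(len(options), p=weights / weights.sum())]
        remaining[key] -= 1
        seq.append(next_c)
        at_c = next_c
    return np.array(seq, dtype=bool)


def generate_sequence(config: SimulationConfig, rng: np.random.Generator | None = None
                      ) -> list[tuple[Congruency, Rsi | None, bool]]:
    """Ordered (congruency, preceding RSI, first-after-break) condition list.

    With ``counterbalance_transitions`` the four congruency transition types
    occur equally often (up to +-1) and the congruent trial count is exactly
    ``n_trials // 2``; otherwise congruency is i.i.d. Bernoulli.  RSI classes
    are balanced within congruency (up to +-1) and randomly ordered; the
    session's first trial has no preceding RSI.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_trials
    if config.counterbalance_transitions and config.p_congruent == 0.5:
        first_c, counts = _transition_counts(n, rng)
        is_con = _walk_transitions(first_c, counts, rng)
    else:
        is_con = rng.random(n) < config.p_congruent

    rsi = np.empty(n, dtype=object)
    rsi[0] = None
    for cong_val in (True, False):
        idx = np.flatnonzero(is_con == cong_val)
        idx = idx[idx > 0]
        half = len(idx) // 2
        pool = np.array([Rsi.SHORT] * half + [Rsi.LONG] * (len(idx) - half), dtype=object)
        rng.shuffle(pool)
        rsi[idx] = pool

    out = []
    for i in range(n):
        first_after_break = i > 0 and config.break_every > 0 and i % config.break_every == 0
        out.append(
            (
                Congruency.CONGRUENT if is_con[i] else Congruency.INCONGRUENT,
                rsi[i],
                first_after_break,
            )
        )
    return out


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _EPS, 1 - _EPS)
    return np.log(p / (1 - p))


def _drift_terms(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial additive (rt_ms, error log-odds) drift offsets, centred."""
    n = config.n_trials
    d = config.drift
    if d.kind is DriftKind.NONE or n == 1:
        return np.zeros(n), np.zeros(n)
    if d.kind is DriftKind.LINEAR:
        ramp = np.arange(n) / (n - 1) - 0.5
        return d.rt_delta_ms * ramp, d.error_logodds_delta * ramp
    phase_len = d.phase_length or max(1, n // 2)
    sign = np.where((np.arange(n) // phase_len) % 2 == 0, 0.5, -0.5)
    return d.rt_delta_ms * sign, -d.error_logodds_delta * sign


def simulate_participant(config: SimulationConfig,
                         participant_id: str = "sim") -> ParticipantDataset:
    """Simulate one session under the configured generative model.

    Accuracy: the error probability of trial ``t`` is the congruency base
    rate, shifted by ``+- adaptation_increment / 2`` when the previous trial
    was congruent / incongruent (conflict adaptation), with drift entering on
    the log-odds scale.  RT: drawn from the trial's congruency x RSI
    component, plus the injected post-error slowing when the previous trial
    was an error, plus the RT drift.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    sequence = generate_sequence(config, rng)
    n = config.n_trials
    is_con = np.array([c is Congruency.CONGRUENT for c, _, _ in sequence])

    rt_drift, err_drift = _drift_terms(config)

    base = np.where(
        is_con,
        config.error_base[Congruency.CONGRUENT],
        config.error_base[Congruency.INCONGRUENT],
    )
    adapt = np.zeros(n)
    if config.adaptation_increment != 0.0:
        prev_con = np.roll(is_con, 1)
        adapt[1:] = config.adaptation_increment * (prev_con[1:].astype(float) - 0.5)
    p_err = 1 / (1 + np.exp(-(_logit(np.clip(base + adapt, _EPS, 1 - _EPS)) + err_drift)))
    is_err = rng.random(n) < p_err
    no_resp = (
        rng.random(n) < config.no_response_prob
        if config.no_response_prob > 0
        else np.zeros(n, dtype=bool)
    )

    # RT components per condition cell; the first trial (no preceding RSI)
    # borrows the short-RSI component of its congruency.
    mu = np.empty(n)
    sigma = np.empty(n)
    tau = np.empty(n)
    for i, (cong, rsi, _) in enumerate(sequence):
        params = config.rt_model[(cong, rsi if rsi is not None else Rsi.SHORT)]
        mu[i], sigma[i], tau[i] = params.mu_ms, params.sigma_ms, params.tau_ms
    rt = mu + sigma * rng.standard_normal(n)
    if np.any(tau > 0):
        rt = rt + np.where(tau > 0, rng.exponential(1.0, size=n) * tau, 0.0)
    prev_err = np.roll(is_err & ~no_resp, 1)
    prev_err[0] = False
    slow = np.where(
        is_con,
        config.pes_ms[Congruency.CONGRUENT],
        config.pes_ms[Congruency.INCONGRUENT],
    )
    rt = rt + np.where(prev_err, slow, 0.0) + rt_drift
    rt = np.maximum(rt, 1.0)

    trials = []
    for i, (cong, rsi, fab) in enumerate(sequence):
        if no_resp[i]:
            accuracy, rt_val = Accuracy.NO_RESPONSE, None
        else:
            accuracy = Accuracy.ERROR if is_err[i] else Accuracy.CORRECT
            rt_val = float(np.round(rt[i], 3))
        trials.append(
            TrialRecord(
                participant_id=participant_id,
                trial_index=i + 1,
                block_index=(i // config.break_every) + 1 if config.break_every > 0 else 1,
                congruency=cong,
                preceding_rsi=rsi,
                rt_ms=rt_val,
                accuracy=accuracy,
                first_after_break=fab,
            )
        )
    return ParticipantDataset(
        participant_id=participant_id,
        trials=trials,
        metadata={"seed": config.seed},
    )


def simulate_study(config: SimulationConfig, n_participants: int,
                   seed: int | None = None) -> list[ParticipantDataset]:
    """Simulate ``n_participants`` independent sessions.

    Each participant gets a child seed spawned deterministically from
    ``seed`` (default: the config's seed), so studies are reproducible and
    participants mutually independent.
    """
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    children = root.spawn(n_participants)
    out = []
    for i, child in enumerate(children):
        child_seed = int(child.generate_state(1, dtype=np.uint32)[0]) % (2**31)
        out.append(
            simulate_participant(
                replace(config, seed=child_seed), participant_id=f"sim{i + 1:04d}"
            )
        )
    return out


def scenario_presets() -> dict[str, SimulationConfig]:
    """Named study conditions.

    * ``paper_like`` -- reference task: adaptation on, 50-ms injected
      slowing, no drifts.  Produces congruent surpluses in all three trial
      types, larger at the long RSI.
    * ``null_pes`` -- no injected slowing; corrected robust PES ~ 0.
    * ``fatigue_confound`` -- adaptation off, linear slowing + rising error
      rate across the session; inflates traditional uncorrected PES while
      robust estimators resist.
    * ``caution_confound`` -- adaptation off, careful (slow, accurate) first
      half then sloppy second half; deflates traditional PES.
    * ``strong_adaptation`` -- doubled conflict-adaptation gap, for
      stress-testing imbalance diagnostics.
    """
    base = SimulationConfig()
    no_pes = {Congruency.CONGRUENT: 0.0, Congruency.INCONGRUENT: 0.0}
    return {
        "paper_like": base,
        "null_pes": replace(base, pes_ms=no_pes),
        "fatigue_confound": replace(
            base,
            adaptation_increment=0.0,
            drift=DriftConfig(kind=DriftKind.LINEAR, rt_delta_ms=80.0,
                              error_logodds_delta=1.5),
        ),
        "caution_confound": replace(
            base,
            adaptation_increment=0.0,
            drift=DriftConfig(kind=DriftKind.PHASE, rt_delta_ms=80.0,
                              error_logodds_delta=1.5, phase_length=544),
        ),
        "strong_adaptation": replace(base, adaptation_increment=0.074),
    }
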