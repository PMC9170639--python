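"""Shared fixtures: worked-example trial logs and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from peskit import (
    Accuracy,
    Congruency,
    ParticipantDataset,
    Rsi,
    TrialRecord,
)

CON, INCON = Congruency.CONGRUENT, Congruency.INCONGRUENT


def make_dataset(accuracies, congruencies=None, rts=None, rsis=None,
                 participant_id="p1", first_after_break=None) -> ParticipantDataset:
    """Build a session from parallel per-trial value lists.

    ``accuracies`` uses 'C'/'E'/'N' shorthand or Accuracy members; unspecified
    congruency alternates, RTs default to 500 ms, RSI defaults to short.
    """
    shorthand = {"C": Accuracy.CORRECT, "E": Accuracy.ERROR, "N": Accuracy.NO_RESPONSE}
    acc = [shorthand.get(a, a) for a in accuracies]
    n = len(acc)
    congruencies = congruencies or [CON if i % 2 == 0 else INCON for i in range(n)]
    rts = rts if rts is not None else [500.0] * n
    rsis = rsis or [None] + [Rsi.SHORT] * (n - 1)
    fab = first_after_break or [False] * n
    trials = [
        TrialRecord(
            participant_id=participant_id,
            trial_index=i + 1,
            congruency=congruencies[i],
            preceding_rsi=rsis[i],
            rt_ms=None if acc[i] is Accuracy.NO_RESPONSE else float(rts[i]),
            accuracy=acc[i],
            first_after_break=fab[i],
        )
        for i in range(n)
    ]
    return ParticipantDataset(participant_id=participant_id, trials=trials)


def worked_example_dataset(pre_cells, post_cells, rsi=Rsi.LONG,
                           filler_rt=1000.0) -> ParticipantDataset:
    """Encode listed pre-error / post-error trial sets as an actual session.

    ``pre_cells`` / ``post_cells``: list of (congruency, rt, count).  Each
    error is embedded in a [filler, pre-error, error, post-error, filler]
    quintuple so that classification recovers exactly the listed trials.
    """
    pres = [(c, rt) for c, rt, n in pre_cells for _ in range(n)]
    posts = [(c, rt) for c, rt, n in post_cells for _ in range(n)]
    assert len(pres) == len(posts)
    acc, cong, rts = [], [], []
    for (pc, prt), (qc, qrt) in zip(pres, posts):
        acc += ["C", "C", "E", "C", "C"]
        cong += [CON, pc, INCON, qc, CON]
        rts += [filler_rt, prt, 800.0, qrt, filler_rt]
    n = len(acc)
    return make_dataset(acc, cong, rts, rsis=[None] + [rsi] * (n - 1))


@pytest.fixture
def balanced_example():
    """Balanced worked example: 10+10 pre-error, 10+10 post-error trials."""
    return worked_example_dataset(
        pre_cells=[(CON, 1000.0, 10), (INCON, 1200.0, 10)],
        post_cells=[(CON, 1100.0, 10), (INCON, 1300.0, 10)],
    )


@pytest.fixture
def imbalanced_example():
    """Imbalanced worked example: 15 congruent / 5 incongruent pre-error."""
    return worked_example_dataset(
        pre_cells=[(CON, 1000.0, 15), (INCON, 1200.0, 5)],
        post_cells=[(CON, 1100.0, 10), (INCON, 1300.0, 10)],
    )


def oracle_roles(acc: list[str]) -> list[dict]:
    """Brute-force triple-scan role enumerator, independent of the package.

    Checks each (t-1, t, t+1) window literally against the definitions,
    including the error-correct-error ambiguity rule and no-response
    poisoning of neighbour-dependent roles.
    """
    n = len(acc)
    out = []
    for i in range(n):
        prev = acc[i - 1] if i > 0 else None
        nxt = acc[i + 1] if i < n - 1 else None
        r = {"error": False, "post_correct": False, "pre_error": False,
             "post_error": False, "ambiguous": False}
        if acc[i] == "E":
            r["error"] = True
        elif acc[i] == "C":
            if prev == "E" and nxt == "E":
                r["ambiguous"] = True
            else:
                if prev == "C":
                    r["post_correct"] = True
                    if nxt == "E":
                        r["pre_error"] = True
                if prev == "E" and nxt == "C":
                    r["post_error"] = True
        out.append(r)
    return out


def random_accuracy_sequences(n_sequences: int, length: int, seed: int):
    """Random C/E/N sequences with error-heavy and no-response-bearing mixes."""
    rng = np.random.default_rng(seed)
    for _ in range(n_sequences):
        p_err = rng.uniform(0.05, 0.5)
        p_nr = rng.choice([0.0, 0.05])
        u = rng.random(length)
        yield [
            "N" if x < p_nr else ("E" if x < p_nr + p_err else "C") for x in u
        ]
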