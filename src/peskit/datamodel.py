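"""Trial-level data model and delimited-text I/O for speeded interference tasks.

A session is a sequence of trials, each with a congruency condition (do the
flanking distractors agree with the target?), the response--stimulus interval
(RSI) class that *preceded* the trial, a reaction time in milliseconds, and an
accuracy outcome.  The model is deliberately small: everything downstream
(sequence classification, post-error slowing estimation) is a pure function of
these fields.

Trial logs are plain CSV/TSV with one row per trial and fixed lowercase
snake-case headers (see :data:`COLUMNS`).  Alternate headers can be mapped via
``column_map``.  ``read_trial_log`` and ``write_trial_log`` round-trip
losslessly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Congruency",
    "Rsi",
    "Accuracy",
    "Distance",
    "TrialRecord",
    "ParticipantDataset",
    "SchemaError",
    "IntegrityError",
    "RowValidationError",
    "read_trial_log",
    "write_trial_log",
    "datasets_to_frame",
    "frame_to_datasets",
]


class Congruency(str, enum.Enum):
    CONGRUENT = "congruent"
    INCONGRUENT = "incongruent"


class Rsi(str, enum.Enum):
    """Class of the response--stimulus interval preceding a trial."""

    SHORT = "short"
    LONG = "long"


class Accuracy(str, enum.Enum):
    CORRECT = "correct"
    ERROR = "error"
    NO_RESPONSE = "no_response"


class Distance(str, enum.Enum):
    """Flanker--target distance (carried through, not analysed separately)."""

    CLOSE = "close"
    FAR = "far"


class SchemaError(ValueError):
    """A required column is missing or has an unusable dtype."""


class IntegrityError(ValueError):
    """Cross-row consistency violated (duplicate or unordered trial indices)."""


class RowValidationError(ValueError):
    """One or more rows carry invalid values; lists the offending row numbers."""

    def __init__(self, message: str, rows: Sequence[int]):
        super().__init__(f"{message} (rows: {list(rows)})")
        self.rows = list(rows)


#: Canonical column order of a trial log.
COLUMNS = [
    "participant_id",
    "trial_index",
    "block_index",
    "congruency",
    "distance",
    "preceding_rsi",
    "rt_ms",
    "accuracy",
    "first_after_break",
]

_REQUIRED = ["participant_id", "trial_index", "congruency", "preceding_rsi", "rt_ms", "accuracy"]


@dataclass(frozen=True)
class TrialRecord:
    """One observed trial.

    ``preceding_rsi`` is the RSI class of the interval before THIS trial's
    stimulus; it may be ``None`` only on the session's first trial.  ``rt_ms``
    is ``None`` exactly when ``accuracy`` is ``no_response``.
    """

    participant_id: str
    trial_index: int
    congruency: Congruency
    accuracy: Accuracy
    rt_ms: float | None = None
    preceding_rsi: Rsi | None = None
    block_index: int = 1
    distance: Distance = Distance.CLOSE
    first_after_break: bool = False

    def __post_init__(self) -> None:
        if (self.rt_ms is None) != (self.accuracy is Accuracy.NO_RESPONSE):
            raise ValueError(
                f"trial {self.trial_index}: rt_ms must be absent iff accuracy is no_response"
            )


@dataclass
class ParticipantDataset:
    """An ordered session of trials for one participant."""

    participant_id: str
    trials: list[TrialRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = {t.participant_id for t in self.trials}
        if ids - {self.participant_id}:
            raise IntegrityError(
                f"trials carry foreign participant ids {sorted(ids - {self.participant_id})}"
            )
        idx = [t.trial_index for t in self.trials]
        if sorted(idx) != idx:
            self.trials = sorted(self.trials, key=lambda t: t.trial_index)
            idx = [t.trial_index for t in self.trials]
        if len(set(idx)) != len(idx):
            dupes = sorted({i for i in idx if idx.count(i) > 1})
            raise IntegrityError(
                f"participant {self.participant_id}: duplicate trial_index {dupes}"
            )
        missing_rsi = [t.trial_index for t in self.trials[1:] if t.preceding_rsi is None]
        if missing_rsi:
            raise IntegrityError(
                f"participant {self.participant_id}: preceding_rsi missing on "
                f"non-initial trials {missing_rsi}"
            )

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-trial DataFrame in canonical column order."""
        rows = [
            {
                "participant_id": t.participant_id,
                "trial_index": t.trial_index,
                "block_index": t.block_index,
                "congruency": t.congruency.value,
                "distance": t.distance.value,
                "preceding_rsi": t.preceding_rsi.value if t.preceding_rsi else "",
                "rt_ms": np.nan if t.rt_ms is None else float(t.rt_ms),
                "accuracy": t.accuracy.value,
                "first_after_break": int(t.first_after_break),
            }
            for t in self.trials
        ]
        return pd.DataFrame(rows, columns=COLUMNS)


def _parse_enum(value, enum_cls, column: str, row: int):
    try:
        return enum_cls(str(value).strip().lower())
    except ValueError:
        raise RowValidationError(
            f"invalid {column} value {value!r} "
            f"(expected one of {[e.value for e in enum_cls]})",
            [row],
        ) from None


def frame_to_datasets(df: pd.DataFrame, *, rsi_threshold_ms: float | None = None
                      ) -> list[ParticipantDataset]:
    """Build validated :class:`ParticipantDataset` objects from a tidy frame.

    If ``rsi_threshold_ms`` is given, a numeric ``preceding_rsi`` column (in
    ms) is accepted and binned: values < threshold become ``short``, others
    ``long``.
    """
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df = df.copy()
    if "block_index" not in df.columns:
        df["block_index"] = 1
    if "distance" not in df.columns:
        df["distance"] = Distance.CLOSE.value
    if "first_after_break" not in df.columns:
        df["first_after_break"] = 0

    datasets: list[ParticipantDataset] = []
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("trial_index")
        if grp["trial_index"].duplicated().any():
            dupes = sorted(grp.loc[grp["trial_index"].duplicated(), "trial_index"].unique())
            raise IntegrityError(f"participant {pid}: duplicate trial_index {dupes}")
        trials = []
        first_index = grp["trial_index"].iloc[0]
        for rownum, row in grp.iterrows():
            accuracy = _parse_enum(row["accuracy"], Accuracy, "accuracy", rownum)
            rt_raw = row["rt_ms"]
            rt: float | None
            if accuracy is Accuracy.NO_RESPONSE:
                rt = None
            else:
                try:
                    rt = float(rt_raw)
                except (TypeError, ValueError):
                    rt = np.nan
                if not np.isfinite(rt):
                    raise RowValidationError(
                        f"non-numeric rt_ms {rt_raw!r} on a responded trial", [rownum]
                    )
            rsi_raw = row["preceding_rsi"]
            if pd.isna(rsi_raw) or str(rsi_raw).strip() == "":
                if row["trial_index"] != first_index:
                    raise IntegrityError(
                        f"participant {pid}: preceding_rsi missing on trial "
                        f"{row['trial_index']}"
                    )
                rsi = None
            elif rsi_threshold_ms is not None and str(rsi_raw).replace(".", "", 1).isdigit():
                rsi = Rsi.SHORT if float(rsi_raw) < rsi_threshold_ms else Rsi.LONG
            else:
                rsi = _parse_enum(rsi_raw, Rsi, "preceding_rsi", rownum)
            trials.append(
                TrialRecord(
                    participant_id=str(pid),
                    trial_index=int(row["trial_index"]),
                    block_index=int(row["block_index"]),
                    congruency=_parse_enum(row["congruency"], Congruency, "congruency", rownum),
                    distance=_parse_enum(row["distance"], Distance, "distance", rownum),
                    preceding_rsi=rsi,
                    rt_ms=rt,
                    accuracy=accuracy,
                    first_after_break=bool(int(row["first_after_break"])),
                )
            )
        datasets.append(ParticipantDataset(participant_id=str(pid), trials=trials))
    return datasets


def read_trial_log(path: str | Path, *, sep: str | None = None,
                   column_map: Mapping[str, str] | None = None,
                   rsi_threshold_ms: float | None = None) -> list[ParticipantDataset]:
    """Read a delimited trial log into one dataset per participant.

    Parameters
    ----------
    path : str or Path
        CSV/TSV file with one row per trial.
    sep : str, optional
        Field delimiter; inferred from the extension when omitted
        (``.tsv``/``.tab`` → tab, else comma).
    column_map : mapping, optional
        ``{file_header: canonical_name}`` for logs with alternate headers.
    rsi_threshold_ms : float, optional
        Accept a numeric RSI column (ms) and bin it at this threshold.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"participant_id": str})
    if column_map:
        df = df.rename(columns=dict(column_map))
    return frame_to_datasets(df, rsi_threshold_ms=rsi_threshold_ms)


def datasets_to_frame(datasets: Iterable[ParticipantDataset]) -> pd.DataFrame:
    frames = [d.to_frame() for d in datasets]
    if not frames:
        return pd.DataFrame(columns=COLUMNS)
    return pd.concat(frames, ignore_index=True)


def write_trial_log(datasets: Iterable[ParticipantDataset], path: str | Path,
                    *, sep: str = ",") -> Path:
    """Write datasets to a delimited trial log (lossless round-trip)."""
    path = Path(path)
    df = datasets_to_frame(datasets)
    df.to_csv(path, sep=sep, index=False)
    return path
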