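"""Trial records, regressor encoding, and the trial-log file format.

A behavioral session is an ordered sequence of two-alternative forced-choice
(2AFC) trials.  Each trial presents a stimulus (one or more named dimensions,
each graded in [-1, +1]), has a correct ("instructed") side, and records the
subject's choice and outcome.  Choices feed a linear decision model through a
fixed set of named regressors:

``bias``
    constant 1.
``S0`` (and any other stimulus dimension, e.g. ``T0``, ``orient``, ``freq``)
    the current trial's graded stimulus value; -1 instructs left, +1 right.
``S1``
    the previous trial's stimulus value (instructed-side sign when the
    previous stimulus has no ``S0`` dimension).
``A1``
    previous action: -1 left, +1 right.
``R1``
    previous reward: +1 rewarded, -1 not.
``WSLS``
    win-stay/lose-switch, the product ``A1 * R1``.

History regressors are 0 on the first trial of a log and whenever the
previous trial was a no-response trial.

Logs are stored as UTF-8 CSV (one row per trial, stimulus dimensions in
``stim:<dim>`` columns) with a JSON sidecar for session metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

LEFT = "left"
RIGHT = "right"
NONE = "none"

CORRECT = "correct"
ERROR = "error"
NO_RESPONSE = "no_response"

#: default regressor set for frequency 2AFC tasks
DEFAULT_REGRESSORS: tuple[str, ...] = ("bias", "S0", "S1", "A1", "R1", "WSLS")
#: delayed-comparison (working-memory) variant with a second stimulus T0
WM_REGRESSORS: tuple[str, ...] = ("bias", "S0", "T0", "S1", "A1", "R1", "WSLS")

_HISTORY = ("S1", "A1", "R1", "WSLS")

#: graded value map for the working-memory stimulus frequencies
WM_FREQ_VALUES: dict[float, float] = {8: -1.0, 16: -0.5, 32: 0.0, 64: 0.5, 128: 1.0}


class TrialValidationError(ValueError):
    """A trial record violates the outcome/choice/reward invariants."""


class TrialLogParseError(ValueError):
    """A trial-log file is malformed; the message names the offending row."""


def side_sign(side: str) -> int:
    """Map a side label to the package-wide sign convention (right = +1)."""
    if side == LEFT:
        return -1
    if side == RIGHT:
        return +1
    raise ValueError(f"not a side: {side!r}")


def sign_side(sign: float) -> str:
    return RIGHT if sign > 0 else LEFT


@dataclass
class TrialRecord:
    """One trial: stimulus, contingency, and realized behavior."""

    index: int
    stimulus: dict[str, float]
    correct_side: str
    choice: str
    rewarded: bool
    outcome: str
    protocol_id: str = ""
    timestamp: float | None = None

    def validate(self) -> None:
        if self.correct_side not in (LEFT, RIGHT):
            raise TrialValidationError(
                f"trial {self.index}: bad correct_side {self.correct_side!r}")
        if self.choice not in (LEFT, RIGHT, NONE):
            raise TrialValidationError(
                f"trial {self.index}: bad choice {self.choice!r}")
        if self.outcome not in (CORRECT, ERROR, NO_RESPONSE):
            raise TrialValidationError(
                f"trial {self.index}: bad outcome {self.outcome!r}")
        if (self.outcome == NO_RESPONSE) != (self.choice == NONE):
            raise TrialValidationError(
                f"trial {self.index}: outcome {self.outcome!r} inconsistent "
                f"with choice {self.choice!r}")
        if self.rewarded and self.outcome != CORRECT:
            raise TrialValidationError(
                f"trial {self.index}: rewarded trial with outcome {self.outcome!r}")
        for dim, value in self.stimulus.items():
            if not -1.0 <= float(value) <= 1.0:
                raise TrialValidationError(
                    f"trial {self.index}: stimulus {dim}={value} outside [-1, 1]")

    @property
    def is_choice_trial(self) -> bool:
        return self.outcome != NO_RESPONSE

    def stimulus_value(self) -> float:
        """Primary stimulus value: the S0 dimension, else the instructed side."""
        if "S0" in self.stimulus:
            return float(self.stimulus["S0"])
        return float(side_sign(self.correct_side))


@dataclass
class FeatureVector:
    """Ordered, named regressor values for one trial."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("names and values length mismatch")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def dot(self, weights: np.ndarray) -> float:
        return float(np.dot(np.asarray(weights, dtype=float), self.values))


@dataclass
class TrialLog:
    """Ordered trial sequence plus session metadata."""

    trials: list[TrialRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    def __getitem__(self, i: int) -> TrialRecord:
        return self.trials[i]

    def __iter__(self) -> Iterator[TrialRecord]:
        return iter(self.trials)

    def append(self, record: TrialRecord) -> None:
        expected = len(self.trials)
        if record.index != expected:
            raise TrialValidationError(
                f"trial index {record.index} breaks contiguity (expected {expected})")
        record.validate()
        self.trials.append(record)

    def choice_trials(self) -> list[TrialRecord]:
        """Trials on which a choice was made, original order preserved."""
        return [t for t in self.trials if t.is_choice_trial]

    def validate(self) -> None:
        for expected, t in enumerate(self.trials):
            if t.index != expected:
                raise TrialValidationError(
                    f"trial index {t.index} breaks contiguity (expected {expected})")
            t.validate()


def _encode_history(prev: TrialRecord | None) -> dict[str, float]:
    if prev is None or prev.outcome == NO_RESPONSE:
        return {name: 0.0 for name in _HISTORY}
    a1 = float(side_sign(prev.choice))
    r1 = 1.0 if prev.rewarded else -1.0
    return {"S1": prev.stimulus_value(), "A1": a1, "R1": r1, "WSLS": a1 * r1}


def encode_stimulus(
    stimulus: Mapping[str, float],
    prev: TrialRecord | None,
    regressor_set: Sequence[str] = DEFAULT_REGRESSORS,
) -> FeatureVector:
    """Encode a (possibly hypothetical) trial's stimulus against a given history.

    ``prev`` is the previous realized trial, or None for a cold start.  Used
    both by :func:`encode_regressors` and by the teacher to score candidate
    trials before they are run.
    """
    history = _encode_history(prev)
    values = []
    for name in regressor_set:
        if name == "bias":
            values.append(1.0)
        elif name in stimulus:
            values.append(float(stimulus[name]))
        elif name in history:
            values.append(history[name])
        else:
            raise KeyError(
                f"unknown regressor {name!r}: not bias, a stimulus dimension "
                f"{sorted(stimulus)}, or a history regressor {_HISTORY}")
    return FeatureVector(tuple(regressor_set), np.array(values))


def encode_regressors(
    log_or_trials: TrialLog | Sequence[TrialRecord],
    i: int,
    regressor_set: Sequence[str] = DEFAULT_REGRESSORS,
) -> FeatureVector:
    """Feature vector for trial ``i`` of a log; history comes from trial ``i-1``."""
    trials = log_or_trials.trials if isinstance(log_or_trials, TrialLog) else log_or_trials
    if not 0 <= i < len(trials):
        raise IndexError(f"trial index {i} out of range")
    prev = trials[i - 1] if i > 0 else None
    return encode_stimulus(trials[i].stimulus, prev, regressor_set)


def design_matrix(
    trials: Sequence[TrialRecord],
    regressor_set: Sequence[str] = DEFAULT_REGRESSORS,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack features and choice labels (+1 right, -1 left) for a trial sequence.

    History regressors are taken from the preceding element of ``trials``, so
    pass an already-preprocessed (choice-trials-only) sequence for offline fits.
    """
    X = np.empty((len(trials), len(regressor_set)))
    y = np.empty(len(trials))
    for i, t in enumerate(trials):
        X[i] = encode_regressors(trials, i, regressor_set).values
        y[i] = side_sign(t.choice) if t.choice != NONE else 0.0
    return X, y


# ---------------------------------------------------------------------------
# file format

_CORE_COLUMNS = ("index", "protocol_id", "correct_side", "choice",
                 "rewarded", "outcome", "timestamp")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_trial_log(log: TrialLog, path: str | Path) -> None:
    """Write a log as CSV plus a ``<path>.meta.json`` metadata sidecar."""
    path = Path(path)
    dims = sorted({d for t in log.trials for d in t.stimulus})
    rows = []
    for t in log.trials:
        row: dict = {
            "index": t.index,
            "protocol_id": t.protocol_id,
            "correct_side": t.correct_side,
            "choice": t.choice,
            "rewarded": t.rewarded,
            "outcome": t.outcome,
            "timestamp": "" if t.timestamp is None else t.timestamp,
        }
        for d in dims:
            row[f"stim:{d}"] = t.stimulus.get(d, "")
        rows.append(row)
    columns = list(_CORE_COLUMNS[:2]) + [f"stim:{d}" for d in dims] + \
        list(_CORE_COLUMNS[2:])
    extra = log.metadata.get("extra_columns", {})
    columns += list(extra)
    frame = pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(columns=columns)
    for col, vals in extra.items():
        frame[col] = vals
    frame.to_csv(path, index=False)
    meta = {k: v for k, v in log.metadata.items() if k != "extra_columns"}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_trial_log(path: str | Path) -> TrialLog:
    """Read a trial-log CSV (and its metadata sidecar, if present)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, keep_default_na=False, na_values=[""])
    except pd.errors.EmptyDataError:
        frame = pd.DataFrame()
    metadata: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        metadata.update(json.loads(sidecar.read_text()))
    log = TrialLog(metadata=metadata)
    if frame.empty:
        return log
    known = set(_CORE_COLUMNS)
    stim_cols = [c for c in frame.columns if c.startswith("stim:")]
    extra_cols = [c for c in frame.columns if c not in known and c not in stim_cols]
    for row_no, row in enumerate(frame.itertuples(index=False)):
        rec = row._asdict() if hasattr(row, "_asdict") else dict(zip(frame.columns, row))
        rec = dict(zip(frame.columns, row))
        try:
            stimulus = {}
            for c in stim_cols:
                v = rec[c]
                if v == v and v != "":  # not NaN / blank
                    stimulus[c[len("stim:"):]] = float(v)
            ts = rec.get("timestamp", "")
            record = TrialRecord(
                index=int(rec["index"]),
                stimulus=stimulus,
                correct_side=str(rec["correct_side"]),
                choice=str(rec["choice"]),
                rewarded=_parse_bool(rec["rewarded"]),
                outcome=str(rec["outcome"]),
                protocol_id=str(rec.get("protocol_id", "") or ""),
                timestamp=None if ts != ts or ts == "" else float(ts),
            )
        except (KeyError, ValueError, TypeError) as exc:
            if isinstance(exc, TrialValidationError):
                raise
            raise TrialLogParseError(f"row {row_no}: {exc}") from exc
        log.append(record)
    if extra_cols:
        log.metadata["extra_columns"] = {c: list(frame[c]) for c in extra_cols}
    return log


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    raise ValueError(f"not a boolean: {v!r}")
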