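"""Simulated learners ("students") and synthetic behavioral-log generators.

A student is an online linear decision model that (a) converts its decision
variable into a choice and (b) learns from the trial's outcome with the same
momentum/L1 update the teacher assumes.  Two choice policies are provided:

``sample``    choice = right with probability (1 - eps) * sigmoid(<w, x>) + eps/2,
              where eps is a lapse rate (default 0);
``threshold`` choice = sign of <w, x>, random at exactly 0.

By default a student updates toward the *correct* label of the realized trial
(reward feedback reveals it in these tasks); ``learn_from="choice"`` gives a
choice-supervised variant.

The module also generates fixture logs from a fixed ground-truth model — the
known-weights data used by the offline analysis tests — and synthetic
event-train sessions for psychophysical-kernel recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .online_model import Hyper, ModelState, sigmoid, update
from .trial_data import (CORRECT, DEFAULT_REGRESSORS, ERROR, NONE,
                         NO_RESPONSE, FeatureVector, TrialLog, TrialRecord,
                         encode_stimulus, sign_side)

SAMPLE = "sample"
THRESHOLD = "threshold"


@dataclass
class StudentSpec:
    """Configuration of a simulated learner."""

    regressors: tuple[str, ...] = DEFAULT_REGRESSORS
    initial_weights: Mapping[str, float] = field(default_factory=dict)
    hyper: Hyper = field(default_factory=lambda: Hyper(alpha=0.1, eta=0.9, lam=0.1))
    choice_policy: str = SAMPLE
    lapse: float = 0.0
    learn_from: str = "correct"  # or "choice"

    def __post_init__(self) -> None:
        if self.choice_policy not in (SAMPLE, THRESHOLD):
            raise ValueError(f"unknown choice policy {self.choice_policy!r}")
        if not 0.0 <= self.lapse < 0.5:
            raise ValueError(f"lapse must lie in [0, 0.5), got {self.lapse}")
        if self.learn_from not in ("correct", "choice"):
            raise ValueError(f"learn_from must be 'correct' or 'choice'")


class Student:
    """A simulated subject: chooses on, then learns from, each trial."""

    def __init__(self, spec: StudentSpec):
        self.spec = spec
        self.state = ModelState.zeros(spec.regressors, dict(spec.initial_weights))

    def p_right(self, x: FeatureVector) -> float:
        return float(sigmoid(x.dot(self.state.w)))

    def choose(self, x: FeatureVector, rng: np.random.Generator) -> int:
        """Return a choice sign (+1 right, -1 left)."""
        z = x.dot(self.state.w)
        if self.spec.choice_policy == THRESHOLD:
            if z == 0.0:
                return 1 if rng.random() < 0.5 else -1
            return 1 if z > 0 else -1
        p = (1.0 - self.spec.lapse) * float(sigmoid(z)) + self.spec.lapse / 2.0
        return 1 if rng.random() < p else -1

    def learn(self, x: FeatureVector, correct_label: int, choice: int) -> None:
        y = correct_label if self.spec.learn_from == "correct" else choice
        self.state = update(self.state, x, y, self.spec.hyper)


def student_choose(student: Student, x: FeatureVector,
                   rng: np.random.Generator) -> int:
    return student.choose(x, rng)


def student_learn(student: Student, x: FeatureVector, y: int) -> Student:
    """Apply one outcome-supervised update in place (returned for chaining)."""
    student.state = update(student.state, x, y, student.spec.hyper)
    return student


# ---------------------------------------------------------------------------
# fixture generators


def generate_fixture_log(
    ground_truth_weights: Mapping[str, float],
    n_trials: int,
    seed: int,
    regressors: Sequence[str] = DEFAULT_REGRESSORS,
    no_response_rate: float = 0.0,
    protocol_id: str = "fixture",
) -> TrialLog:
    """Synthetic 2AFC log whose choices follow a fixed ground-truth model.

    Each trial instructs a uniformly random side (stimulus dimension ``S0`` in
    {-1, +1}); the choice is a Bernoulli draw from sigmoid(<w_true, x>) with x
    encoded from the realized history.  ``no_response_rate`` inserts
    no-response trials at random positions (their history influence follows
    the zeroing convention).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    names = tuple(regressors)
    w = np.array([float(ground_truth_weights.get(nm, 0.0)) for nm in names])
    unknown = set(ground_truth_weights) - set(names)
    if unknown:
        raise KeyError(f"ground-truth weights for unknown regressors {sorted(unknown)}")
    log = TrialLog(metadata={"task": "fixture_2afc", "seed": seed,
                             "ground_truth": dict(ground_truth_weights)})
    prev: TrialRecord | None = None
    for i in range(n_trials):
        s0 = 1.0 if rng.random() < 0.5 else -1.0
        correct = sign_side(s0)
        if rng.random() < no_response_rate:
            rec = TrialRecord(i, {"S0": s0}, correct, NONE, False, NO_RESPONSE,
                              protocol_id)
        else:
            x = encode_stimulus({"S0": s0}, prev, names)
            choice = 1 if rng.random() < sigmoid(x.dot(w)) else -1
            correct_label = int(s0)
            rec = TrialRecord(i, {"S0": s0}, correct, sign_side(choice),
                              choice == correct_label,
                              CORRECT if choice == correct_label else ERROR,
                              protocol_id)
        log.append(rec)
        prev = rec
    return log


def generate_event_log(
    kernel: Sequence[float],
    n_trials: int,
    seed: int,
    event_rate: float = 0.35,
    bias: float = 0.0,
    protocol_id: str = "events",
) -> TrialLog:
    """Synthetic evidence-accumulation session with per-bin event indicators.

    Each trial presents a train of binary events over ``len(kernel)`` time
    bins (stimulus dimensions ``bin00``, ``bin01``, ...).  The agent's choice
    is a Bernoulli draw from sigmoid(bias + sum_b kernel[b] * event[b]); the
    nominal correct side is right when the train carries more events than the
    expected count.  Used to test psychophysical-kernel recovery.
    """
    kernel = np.asarray(kernel, dtype=float)
    n_bins = kernel.size
    rng = np.random.default_rng(seed)
    names = [f"bin{b:02d}" for b in range(n_bins)]
    log = TrialLog(metadata={"task": "event_train", "seed": seed,
                             "n_bins": n_bins, "event_rate": event_rate})
    for i in range(n_trials):
        events = (rng.random(n_bins) < event_rate).astype(float)
        z = bias + float(np.dot(kernel, events))
        choice = 1 if rng.random() < sigmoid(z) else -1
        correct = 1 if events.sum() >= event_rate * n_bins else -1
        stim = dict(zip(names, events))
        log.append(TrialRecord(i, stim, sign_side(correct), sign_side(choice),
                               choice == correct,
                               CORRECT if choice == correct else ERROR,
                               protocol_id))
    return log
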