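"""Trial-selection policies: machine teacher, anti-bias scheduler, random.

The machine teacher maintains a surrogate online model of the subject (fit to
the subject's realized choices) and scores every candidate (stimulus, label)
pair in the task repertoire by how a plain gradient step on that trial would
move the surrogate weights w toward a goal w*:

    ||w' - w*||^2 ~ ||w - w*||^2 + gamma^2 T1(x, y) - 2 gamma T2(x, y)

    T1(x, y | w) = 1 / (1 + e^{y <w, x>})      predicted error probability
    T2(x, y | w) = <w - w*, (<w, x> - y) x>    alignment of the induced update
                                               with the straight path to w*

    next trial = argmin over the repertoire of  gamma^2 T1 - 2 gamma T2

T1 is the probability form used by the deployed selection rule; the exact
quadratic term of the distance decomposition, ||(<w,x> - y) x||^2, is
available as ``t1_form="gradient_norm"``.  The two coincide only in spirit:
both shrink with the margin y<w, x>.

The anti-bias baseline reproduces a three-priority side scheduler: repeat a
side after three straight failures on it, switch after three same-side
rewards, and otherwise sample the left side with a probability built from the
recent per-side correct/error composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .online_model import ModelState, gradient as _loss_gradient
from .trial_data import (LEFT, NO_RESPONSE, RIGHT, FeatureVector, TrialLog,
                         TrialRecord, side_sign)

PROBABILITY = "probability"
GRADIENT_NORM = "gradient_norm"

RULE_CONSTRAINED = "rule_constrained"
FREE = "free"


@dataclass
class CandidateTrial:
    """A scoreable (stimulus, correct-label) pair with history-filled features."""

    stimulus: dict[str, float]
    y: int
    x: FeatureVector
    info: dict = field(default_factory=dict)


@dataclass
class Criterion:
    """Performance criterion over a trailing window of qualifying trials.

    ``difficulty_at_least`` restricts evaluation to repertoire entries whose
    difficulty rank (larger = harder) reaches the given level, e.g. the
    hardest trial types of a graded repertoire.
    """

    window: int = 200
    threshold: float = 0.75
    difficulty_at_least: int | None = None

    def __post_init__(self) -> None:
        if not 0.5 < self.threshold <= 1.0:
            raise ValueError(f"threshold must lie in (0.5, 1], got {self.threshold}")
        if self.window < 1:
            raise ValueError("window must be >= 1")


@dataclass
class GoalSpec:
    """A teaching goal: target weights plus the rule and advancement criteria.

    target      mapping regressor name -> goal weight (unlisted names -> 0)
    rule        stimulus -> correct side sign (+1 right, -1 left)
    criterion   learning-phase advancement criterion
    test_block  optional testing-phase criterion (random trials)
    label_mode  "rule_constrained": candidate labels follow ``rule``;
                "free": both labels enumerated per stimulus
    repertoire  optional stimulus-set override for this goal
    """

    target: Mapping[str, float]
    rule: Callable[[Mapping[str, float]], int] | None = None
    criterion: Criterion | None = None
    test_block: Criterion | None = None
    label_mode: str = RULE_CONSTRAINED
    repertoire: Sequence[Mapping[str, float]] | None = None
    name: str = "goal"

    def target_vector(self, names: Sequence[str]) -> np.ndarray:
        unknown = set(self.target) - set(names)
        if unknown:
            raise KeyError(f"goal targets unknown regressors {sorted(unknown)}")
        return np.array([float(self.target.get(n, 0.0)) for n in names])


# ---------------------------------------------------------------------------
# machine-teaching objective


def difficulty_T1(w: ModelState | np.ndarray, x: FeatureVector, y: int) -> float:
    """Predicted probability of an incorrect response on (x, y)."""
    if y not in (-1, 1):
        raise ValueError(f"label must be -1 or +1, got {y}")
    wv = w.w if isinstance(w, ModelState) else np.asarray(w, dtype=float)
    return float(1.0 / (1.0 + np.exp(y * x.dot(wv))))


def usefulness_T2(w: ModelState | np.ndarray, w_star: np.ndarray,
                  x: FeatureVector, y: int) -> float:
    """Alignment of the induced plain-step update with the path from w to w*."""
    wv = w.w if isinstance(w, ModelState) else np.asarray(w, dtype=float)
    g = _loss_gradient(wv, x.values, y)
    return float(np.dot(wv - np.asarray(w_star, dtype=float), g))


def teaching_objective(w, w_star, x: FeatureVector, y: int, gamma: float,
                       t1_form: str = PROBABILITY) -> float:
    """gamma^2 T1 - 2 gamma T2 for one candidate; lower is better."""
    if t1_form == PROBABILITY:
        t1 = difficulty_T1(w, x, y)
    elif t1_form == GRADIENT_NORM:
        wv = w.w if isinstance(w, ModelState) else np.asarray(w, dtype=float)
        g = _loss_gradient(wv, x.values, y)
        t1 = float(np.dot(g, g))
    else:
        raise ValueError(f"unknown t1_form {t1_form!r}")
    return gamma ** 2 * t1 - 2.0 * gamma * usefulness_T2(w, w_star, x, y)


def select_next_trial(
    w: ModelState | np.ndarray,
    w_star: np.ndarray,
    candidates: Sequence[CandidateTrial],
    gamma: float,
    rng: np.random.Generator,
    t1_form: str = PROBABILITY,
) -> CandidateTrial:
    """Argmin of the teaching objective; exact ties broken uniformly at random."""
    if not candidates:
        raise ValueError("empty candidate repertoire")
    scores = np.array([teaching_objective(w, w_star, c.x, c.y, gamma, t1_form)
                       for c in candidates])
    best = scores.min()
    ties = np.flatnonzero(scores <= best + 1e-12 * max(1.0, abs(best)))
    return candidates[int(rng.choice(ties))]


# ---------------------------------------------------------------------------
# baselines


def random_next(candidates: Sequence[CandidateTrial],
                rng: np.random.Generator) -> CandidateTrial:
    """Uniform draw from the repertoire."""
    if not candidates:
        raise ValueError("empty candidate repertoire")
    return candidates[int(rng.integers(len(candidates)))]


def p_left(trials: Sequence[TrialRecord], n: int = 50) -> float:
    """Left-side sampling probability from the last ``n`` trials.

    P_left = 1/2 * (R_corr / (R_corr + L_corr) + L_err / (L_err + R_err))
    where the four terms count correct/erroneous choices on right/left-type
    trials.  No-response trials carry no correct/error indicator.  A ratio
    with zero denominator is replaced by 1/2.
    """
    recent = trials[-n:]
    l_corr = r_corr = l_err = r_err = 0
    for t in recent:
        if t.outcome == NO_RESPONSE:
            continue
        is_left = t.correct_side == LEFT
        if t.outcome == "correct":
            l_corr += is_left
            r_corr += not is_left
        else:
            l_err += is_left
            r_err += not is_left
    corr_term = r_corr / (r_corr + l_corr) if (r_corr + l_corr) else 0.5
    err_term = l_err / (l_err + r_err) if (l_err + r_err) else 0.5
    return 0.5 * (corr_term + err_term)


def _failure_streak_side(trials: Sequence[TrialRecord]) -> str | None:
    """Side whose last three same-side trials were all errors/no-responses."""
    last_failure_pos = {}
    for side in (LEFT, RIGHT):
        of_side = [(i, t) for i, t in enumerate(trials) if t.correct_side == side]
        if len(of_side) < 3:
            continue
        tail = of_side[-3:]
        if all(t.outcome != "correct" for _, t in tail):
            last_failure_pos[side] = tail[-1][0]
    if not last_failure_pos:
        return None
    # if both sides qualify, repeat the one that failed most recently
    return max(last_failure_pos, key=last_failure_pos.get)


def antibias_next_direction(
    log: TrialLog | Sequence[TrialRecord],
    n: int = 50,
    rng: np.random.Generator | None = None,
) -> str:
    """Next reward direction under the three-priority anti-bias scheduler.

    1. three consecutive failures (error or no response) on one trial type
       -> repeat that type;
    2. three consecutive trials with the same reward direction (no-response
       trials included) -> switch;
    3. otherwise sample left with probability :func:`p_left`.
    """
    trials = log.trials if isinstance(log, TrialLog) else list(log)
    rng = np.random.default_rng() if rng is None else rng
    streak = _failure_streak_side(trials)
    if streak is not None:
        return streak
    if len(trials) >= 3:
        last3 = {t.correct_side for t in trials[-3:]}
        if len(last3) == 1:
            return RIGHT if last3.pop() == LEFT else LEFT
    return LEFT if rng.random() < p_left(trials, n) else RIGHT


# ---------------------------------------------------------------------------
# policy objects used by the closed-loop harness


class MachineTeachingPolicy:
    """Selects the candidate minimizing gamma^2 T1 - 2 gamma T2."""

    name = "machine_teaching"

    def __init__(self, t1_form: str = PROBABILITY):
        self.t1_form = t1_form

    def select(self, candidates, surrogate: ModelState, goal: GoalSpec,
               log: TrialLog, gamma: float, rng) -> CandidateTrial:
        w_star = goal.target_vector(surrogate.names)
        return select_next_trial(surrogate, w_star, candidates, gamma, rng,
                                 self.t1_form)


class RandomPolicy:
    name = "random"

    def select(self, candidates, surrogate, goal, log, gamma, rng) -> CandidateTrial:
        return random_next(candidates, rng)


class AntibiasPolicy:
    """Anti-bias direction scheduler; stimulus drawn uniformly within the side."""

    name = "antibias"

    def __init__(self, n: int = 50):
        self.n = n

    def select(self, candidates, surrogate, goal, log, gamma, rng) -> CandidateTrial:
        direction = antibias_next_direction(log, self.n, rng)
        sign = side_sign(direction)
        sided = [c for c in candidates if c.y == sign]
        return random_next(sided if sided else list(candidates), rng)


POLICIES: dict[str, Callable[[], object]] = {
    "machine_teaching": MachineTeachingPolicy,
    "random": RandomPolicy,
    "antibias": AntibiasPolicy,
}


def make_policy(name: str):
    try:
        return POLICIES[name]()
    except KeyError:
        raise ValueError(
            f"unknown policy {name!r}; choose from {sorted(POLICIES)}") from None
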