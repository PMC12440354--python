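"""Closed-loop training harness: policy x student x task, with advancement.

One simulated trial runs the loop of the deployed training system: the
policy proposes the next (stimulus, reward-direction) pair from the task
repertoire, the student chooses, the outcome is scored, the student learns
from the outcome, and the teacher's surrogate model is updated on the
student's realized choice (choice trials only).  Multi-goal schedules
advance through goals by a two-stage rule: a learning-phase performance
criterion followed by a random-trial testing block with its own criterion.

Three ready-made experiment configurations mirror deployed use:

``working_memory``  delayed frequency comparison on the full 5x5 stimulus
                    matrix (20 trial types, 4 difficulty levels);
                    alpha=0.01, eta=0, gamma=0.03, lam=0.
``2afc``            sound-frequency 2AFC, six-regressor model;
                    alpha=0.1, eta=0.9, gamma=1, lam=0.1.
``dynamic``         two-dimensional 2AFC (frequency x orientation) with three
                    sequential rule goals; same hyperparameters as 2afc.
``simulation``      the 2AFC teacher-student simulation with a noisy student
                    initialized at bias=+2, S1=-2.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .online_model import Hyper, ModelState
from .student_sim import Student, StudentSpec
from .teacher import (Criterion, CandidateTrial, GoalSpec, RandomPolicy,
                      RULE_CONSTRAINED, FREE, make_policy)
from .trial_data import (CORRECT, DEFAULT_REGRESSORS, ERROR, TrialLog,
                         TrialRecord, WM_REGRESSORS, encode_stimulus,
                         sign_side)

CRITERION_MET = "criterion_met"
BUDGET_EXHAUSTED = "budget_exhausted"


@dataclass
class TaskSpec:
    """A task: stimulus repertoire, regressor set, rule and difficulty grading."""

    name: str
    regressors: tuple[str, ...]
    repertoire: list[dict[str, float]]
    rule: Callable[[Mapping[str, float]], int]
    difficulty: Callable[[Mapping[str, float]], int] | None = None

    def __post_init__(self) -> None:
        if not self.repertoire:
            raise ValueError("repertoire must be non-empty")
        for stim in self.repertoire:
            for dim, v in stim.items():
                if not -1.0 <= v <= 1.0:
                    raise ValueError(f"stimulus {dim}={v} outside [-1, 1]")

    def difficulty_rank(self, stimulus: Mapping[str, float]) -> int:
        return 0 if self.difficulty is None else int(self.difficulty(stimulus))


@dataclass
class PhaseResult:
    name: str
    start: int
    end: int  # exclusive
    status: str


@dataclass
class SessionResult:
    """Everything a closed-loop run produced."""

    log: TrialLog
    surrogate: ModelState
    student: Student
    student_weights: np.ndarray   # (n_trials, n_regressors)
    surrogate_weights: np.ndarray
    difficulty: np.ndarray        # selected trial difficulty rank per trial
    status: str
    phases: list[PhaseResult] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.log)


def enumerate_candidates(
    task: TaskSpec,
    goal: GoalSpec,
    prev: TrialRecord | None,
) -> list[CandidateTrial]:
    """Score-ready candidates: repertoire stimuli with history-filled features."""
    rule = goal.rule or task.rule
    repertoire = goal.repertoire if goal.repertoire is not None else task.repertoire
    out = []
    for stim in repertoire:
        labels = (int(rule(stim)),) if goal.label_mode == RULE_CONSTRAINED else (-1, 1)
        for y in labels:
            x = encode_stimulus(stim, prev, task.regressors)
            out.append(CandidateTrial(dict(stim), y, x,
                                      {"difficulty": task.difficulty_rank(stim)}))
    return out


class _CriterionTracker:
    """Trailing-window accuracy over qualifying trials."""

    def __init__(self, criterion: Criterion | None):
        self.criterion = criterion
        self.window: deque[bool] = deque(
            maxlen=criterion.window if criterion else 1)
        self.n_seen = 0

    def record(self, correct: bool, difficulty: int) -> None:
        c = self.criterion
        if c is None:
            return
        if c.difficulty_at_least is not None and difficulty < c.difficulty_at_least:
            return
        self.window.append(correct)
        self.n_seen += 1

    @property
    def met(self) -> bool:
        c = self.criterion
        if c is None or self.n_seen < c.window:
            return False
        return float(np.mean(self.window)) >= c.threshold


def _run_phase(
    log: TrialLog,
    task: TaskSpec,
    policy,
    student: Student,
    surrogate: ModelState,
    goal: GoalSpec,
    criterion: Criterion | None,
    budget: int,
    gamma: float,
    rng: np.random.Generator,
    protocol_id: str,
    recorder: dict,
) -> tuple[ModelState, str]:
    tracker = _CriterionTracker(criterion)
    for _ in range(budget):
        prev = log.trials[-1] if log.trials else None
        candidates = enumerate_candidates(task, goal, prev)
        chosen = policy.select(candidates, surrogate, goal, log, gamma, rng)
        choice = student.choose(chosen.x, rng)
        correct = choice == chosen.y
        rec = TrialRecord(
            index=len(log),
            stimulus=dict(chosen.stimulus),
            correct_side=sign_side(chosen.y),
            choice=sign_side(choice),
            rewarded=correct,
            outcome=CORRECT if correct else ERROR,
            protocol_id=protocol_id,
        )
        log.append(rec)
        student.learn(chosen.x, chosen.y, choice)
        if rec.is_choice_trial:  # simulated students always respond
            surrogate = _surrogate_update(surrogate, chosen.x, choice,
                                          recorder["hyper"])
        recorder["student_w"].append(student.state.w.copy())
        recorder["surrogate_w"].append(surrogate.w.copy())
        recorder["difficulty"].append(chosen.info.get("difficulty", 0))
        tracker.record(correct, chosen.info.get("difficulty", 0))
        if tracker.met:
            return surrogate, CRITERION_MET
    return surrogate, BUDGET_EXHAUSTED


def _stack(rows, width):
    return np.array(rows).reshape(len(rows), width)


def _surrogate_update(surrogate, x, choice, hyper):
    from .online_model import update
    return update(surrogate, x, choice, hyper)


def run_session(
    task: TaskSpec,
    policy,
    student: Student,
    goal: GoalSpec,
    seed: int,
    budget: int = 20_000,
    hyper: Hyper | None = None,
    surrogate: ModelState | None = None,
    protocol_id: str | None = None,
) -> SessionResult:
    """Run one closed-loop phase until the goal criterion or the budget.

    ``hyper`` parameterizes the teacher's surrogate model (defaults to the
    student's own hyperparameters); its ``gamma`` sets the teaching objective
    trade-off.  Budget exhaustion is reported through ``result.status``.
    """
    if isinstance(policy, str):
        policy = make_policy(policy)
    rng = np.random.default_rng(seed)
    hyper = hyper or student.spec.hyper
    surrogate = surrogate or ModelState.zeros(task.regressors)
    log = TrialLog(metadata={"task": task.name, "seed": seed,
                             "policy": getattr(policy, "name", str(policy))})
    recorder = {"student_w": [], "surrogate_w": [], "difficulty": [],
                "hyper": hyper}
    surrogate, status = _run_phase(
        log, task, policy, student, surrogate, goal, goal.criterion, budget,
        hyper.gamma, rng, protocol_id or goal.name, recorder)
    log.metadata["status"] = status
    return SessionResult(
        log=log, surrogate=surrogate, student=student,
        student_weights=_stack(recorder["student_w"], len(student.state.names)),
        surrogate_weights=_stack(recorder["surrogate_w"], len(surrogate.names)),
        difficulty=np.array(recorder["difficulty"], dtype=int),
        status=status,
        phases=[PhaseResult(goal.name, 0, len(log), status)])


def run_goal_schedule(
    task: TaskSpec,
    goals: Sequence[GoalSpec],
    policy,
    student: Student,
    seed: int,
    budget_per_goal: int = 30_000,
    test_budget: int = 2_000,
    hyper: Hyper | None = None,
    reset_surrogate: bool = False,
    advance_on_budget: bool = False,
) -> SessionResult:
    """Run an ordered goal schedule with two-stage advancement.

    Per goal: (1) a learning phase under ``policy`` until the goal's
    criterion is met over a trailing window of choice trials; (2) a testing
    phase with randomly drawn trials until the testing criterion is met over
    its own trailing window (at least that many testing trials are run).
    The surrogate model persists across goals unless ``reset_surrogate``.
    ``advance_on_budget`` moves to the next goal when a phase budget is
    exhausted (status still records the shortfall) — useful for fixed-block
    comparisons; by default the schedule stops.
    """
    if isinstance(policy, str):
        policy = make_policy(policy)
    rng = np.random.default_rng(seed)
    hyper = hyper or student.spec.hyper
    surrogate = ModelState.zeros(task.regressors)
    log = TrialLog(metadata={"task": task.name, "seed": seed,
                             "policy": getattr(policy, "name", str(policy))})
    recorder = {"student_w": [], "surrogate_w": [], "difficulty": [],
                "hyper": hyper}
    phases: list[PhaseResult] = []
    status = CRITERION_MET
    tester = RandomPolicy()
    for goal in goals:
        if reset_surrogate:
            surrogate = ModelState.zeros(task.regressors)
        start = len(log)
        surrogate, st = _run_phase(
            log, task, policy, student, surrogate, goal, goal.criterion,
            budget_per_goal, hyper.gamma, rng, f"{goal.name}:learning", recorder)
        phases.append(PhaseResult(f"{goal.name}:learning", start, len(log), st))
        if st != CRITERION_MET and not advance_on_budget:
            status = st
            break
        if goal.test_block is not None:
            test_goal = _testing_goal(task, goal)
            start = len(log)
            surrogate, st = _run_phase(
                log, task, tester, student, surrogate, test_goal,
                goal.test_block, test_budget, hyper.gamma, rng,
                f"{goal.name}:testing", recorder)
            phases.append(PhaseResult(f"{goal.name}:testing", start, len(log), st))
            if st != CRITERION_MET and not advance_on_budget:
                status = st
                break
    log.metadata["status"] = status
    return SessionResult(
        log=log, surrogate=surrogate, student=student,
        student_weights=_stack(recorder["student_w"], len(student.state.names)),
        surrogate_weights=_stack(recorder["surrogate_w"], len(surrogate.names)),
        difficulty=np.array(recorder["difficulty"], dtype=int),
        status=status, phases=phases)


def _testing_goal(task: TaskSpec, goal: GoalSpec) -> GoalSpec:
    """Random-testing variant of a goal; restricts to the hardest types when
    the learning criterion was difficulty-restricted."""
    repertoire = goal.repertoire if goal.repertoire is not None else task.repertoire
    c = goal.criterion
    if c is not None and c.difficulty_at_least is not None:
        repertoire = [s for s in repertoire
                      if task.difficulty_rank(s) >= c.difficulty_at_least]
    return replace_goal(goal, repertoire=list(repertoire),
                        label_mode=RULE_CONSTRAINED)


def replace_goal(goal: GoalSpec, **kw) -> GoalSpec:
    from dataclasses import replace as _replace
    return _replace(goal, **kw)


# ---------------------------------------------------------------------------
# task builders


def afc2_task() -> TaskSpec:
    """Sound-frequency 2AFC: two trial types, six-regressor model."""
    return TaskSpec(
        name="2afc",
        regressors=DEFAULT_REGRESSORS,
        repertoire=[{"S0": -1.0}, {"S0": 1.0}],
        rule=lambda s: 1 if s["S0"] > 0 else -1,
    )


def working_memory_task() -> TaskSpec:
    """Delayed frequency comparison on the full 5x5 stimulus matrix.

    Both stimuli take graded values {-1, -0.5, 0, 0.5, 1}; the 20 off-diagonal
    pairs form the repertoire.  Correct side: right when the second stimulus
    (T0) exceeds the first (S0).  Difficulty rank 1 (easiest, |S0-T0|=2) to 4
    (hardest, |S0-T0|=0.5); the 8 rank-4 types sit nearest the boundary.
    """
    values = (-1.0, -0.5, 0.0, 0.5, 1.0)
    repertoire = [{"S0": a, "T0": b}
                  for a, b in itertools.product(values, values) if a != b]
    rank = {0.5: 4, 1.0: 3, 1.5: 2, 2.0: 1}

    def difficulty(s: Mapping[str, float]) -> int:
        return rank[round(abs(s["S0"] - s["T0"]), 2)]

    return TaskSpec(
        name="working_memory",
        regressors=WM_REGRESSORS,
        repertoire=repertoire,
        rule=lambda s: 1 if s["T0"] > s["S0"] else -1,
        difficulty=difficulty,
    )


def dynamic_task() -> TaskSpec:
    """Two-dimensional 2AFC: frequency x orientation, four combinations."""
    repertoire = [{"freq": f, "orient": o}
                  for f in (-1.0, 1.0) for o in (-1.0, 1.0)]
    return TaskSpec(
        name="dynamic_2afc",
        regressors=("bias", "freq", "orient", "S1", "A1", "R1", "WSLS"),
        repertoire=repertoire,
        rule=lambda s: 1 if s["orient"] > 0 else -1,  # first-goal rule
    )


def dynamic_goals(target_magnitude: float = 1.0) -> list[GoalSpec]:
    """The three sequential rules: orientation, frequency, reversed frequency.

    The default goal magnitude 1 is the fixed point of the assumed update on
    the +/-1 stimulus encoding: a perfect rule-follower drives the decision
    variable to the label, so its fitted weight converges to 1 on the
    relevant dimension and 0 elsewhere.
    """
    m = target_magnitude
    crit = Criterion(window=500, threshold=0.8)
    test = Criterion(window=100, threshold=0.8)
    return [
        GoalSpec({"orient": m}, rule=lambda s: 1 if s["orient"] > 0 else -1,
                 criterion=crit, test_block=test, label_mode=FREE,
                 name="orientation"),
        GoalSpec({"freq": m}, rule=lambda s: 1 if s["freq"] > 0 else -1,
                 criterion=crit, test_block=test, label_mode=FREE,
                 name="frequency"),
        GoalSpec({"freq": -m}, rule=lambda s: -1 if s["freq"] > 0 else 1,
                 criterion=crit, test_block=test, label_mode=FREE,
                 name="frequency_reversed"),
    ]


# ---------------------------------------------------------------------------
# experiment presets


@dataclass
class ExperimentConfig:
    """A runnable configuration: task, goals, surrogate hyper, student, budget."""

    name: str
    task: TaskSpec
    goals: list[GoalSpec]
    hyper: Hyper
    student_spec: StudentSpec
    budget: int

    def make_student(self) -> Student:
        return Student(self.student_spec)


def preset_configs() -> dict[str, ExperimentConfig]:
    """Ready-to-run configurations of the deployed experiments and simulation.

    Goal weights are the converged weights of a perfect rule-follower under
    the assumed update, which drives the decision variable toward the +/-1
    choice label: magnitude 1 on the relevant +/-1 stimulus dimensions, and
    0.8 on the graded comparison pair of the working-memory task (the
    least-squares slope of sign(T0 - S0) on T0 - S0 over the 20-type
    repertoire), 0 elsewhere.
    """
    m = 1.0
    wm_m = 0.8
    wm = working_memory_task()
    afc = afc2_task()
    dyn = dynamic_task()
    return {
        "working_memory": ExperimentConfig(
            name="working_memory",
            task=wm,
            goals=[GoalSpec({"S0": -wm_m, "T0": wm_m},
                            criterion=Criterion(window=200, threshold=0.75,
                                                difficulty_at_least=4),
                            test_block=Criterion(window=100, threshold=0.75),
                            name="comparison")],
            hyper=Hyper(alpha=0.01, eta=0.0, gamma=0.03, lam=0.0),
            student_spec=StudentSpec(regressors=WM_REGRESSORS,
                                     hyper=Hyper(alpha=0.01, eta=0.0,
                                                 gamma=0.03, lam=0.0)),
            budget=60_000,
        ),
        "2afc": ExperimentConfig(
            name="2afc",
            task=afc,
            goals=[GoalSpec({"S0": m},
                            criterion=Criterion(window=200, threshold=0.75),
                            name="frequency")],
            hyper=Hyper(alpha=0.1, eta=0.9, gamma=1.0, lam=0.1),
            student_spec=StudentSpec(hyper=Hyper(alpha=0.1, eta=0.9,
                                                 gamma=1.0, lam=0.1)),
            budget=20_000,
        ),
        "dynamic": ExperimentConfig(
            name="dynamic",
            task=dyn,
            goals=dynamic_goals(m),
            hyper=Hyper(alpha=0.1, eta=0.9, gamma=1.0, lam=0.1),
            student_spec=StudentSpec(regressors=dyn.regressors,
                                     hyper=Hyper(alpha=0.1, eta=0.9,
                                                 gamma=1.0, lam=0.1)),
            budget=30_000,
        ),
        "simulation": ExperimentConfig(
            name="simulation",
            task=afc,
            goals=[GoalSpec({"S0": m},
                            criterion=Criterion(window=200, threshold=0.75),
                            name="frequency")],
            hyper=Hyper(alpha=0.1, eta=0.9, gamma=1.0, lam=0.1),
            student_spec=StudentSpec(
                initial_weights={"bias": 2.0, "S1": -2.0},
                hyper=Hyper(alpha=0.1, eta=0.9, gamma=1.0, lam=0.1)),
            budget=2_000,
        ),
    }
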