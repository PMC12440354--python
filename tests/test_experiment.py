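import numpy as np

from trialteacher.experiment import (afc2_task, dynamic_task, preset_configs,
                                     run_goal_schedule, run_session,
                                     working_memory_task)
from trialteacher.online_model import Hyper
from trialteacher.student_sim import Student, StudentSpec
from trialteacher.teacher import Criterion, GoalSpec


def afc_goal(criterion=None):
    return GoalSpec({"S0": 1.0}, criterion=criterion, name="frequency")


def capable_student(s0=4.0):
    return Student(StudentSpec(initial_weights={"S0": s0},
                               hyper=Hyper(alpha=0.1, eta=0.9, lam=0.1)))


class TestRunSession:
    def test_zero_budget_yields_an_empty_log(self):
        r = run_session(afc2_task(), "random", capable_student(), afc_goal(),
                        seed=0, budget=0)
        assert r.n_trials == 0 and r.status == "budget_exhausted"

    def test_identical_seeds_give_identical_logs(self):
        runs = [run_session(afc2_task(), "machine_teaching",
                            Student(preset_configs()["simulation"].student_spec),
                            afc_goal(), seed=11, budget=300)
                for _ in range(2)]
        a, b = (tuple((t.correct_side, t.choice, t.outcome) for t in r.log)
                for r in runs)
        assert a == b
        assert np.array_equal(runs[0].student_weights, runs[1].student_weights)

    def test_surrogate_update_count_equals_choice_trials(self):
        r = run_session(afc2_task(), "antibias", capable_student(), afc_goal(),
                        seed=3, budget=250)
        n_choice = sum(t.is_choice_trial for t in r.log)
        assert r.surrogate.t == n_choice == 250

    def test_near_ideal_student_reaches_criterion_under_random_policy(self):
        crit = Criterion(window=200, threshold=0.75)
        r = run_session(afc2_task(), "random",
                        Student(StudentSpec(hyper=Hyper(alpha=0.1, eta=0.9,
                                                        lam=0.1))),
                        afc_goal(crit), seed=5, budget=5000)
        assert r.status == "criterion_met"
        assert r.n_trials < 5000

    def test_weight_trajectories_align_with_the_log(self):
        r = run_session(afc2_task(), "random", capable_student(), afc_goal(),
                        seed=1, budget=40)
        assert r.student_weights.shape == (40, 6)
        assert r.surrogate_weights.shape == (40, 6)


class TestGoalSchedule:
    def test_instant_rule_follower_advances_after_500_plus_100_per_goal(self):
        # a student that always answers by the orientation rule: advancement
        # must happen after exactly 500 learning + 100 testing trials per goal
        task = dynamic_task()
        student = Student(StudentSpec(
            regressors=task.regressors, initial_weights={"orient": 50.0},
            hyper=Hyper(alpha=1e-9), choice_policy="threshold"))
        goal = GoalSpec({"orient": 1.0},
                        rule=lambda s: 1 if s["orient"] > 0 else -1,
                        criterion=Criterion(window=500, threshold=0.8),
                        test_block=Criterion(window=100, threshold=0.8),
                        name="orientation")
        goals = [goal, goal, goal]
        r = run_goal_schedule(task, goals, "random", student, seed=2,
                              budget_per_goal=2000)
        assert r.status == "criterion_met"
        assert r.n_trials == 3 * (500 + 100)
        bounds = [(p.name.split(":")[1], p.end - p.start) for p in r.phases]
        assert bounds == [("learning", 500), ("testing", 100)] * 3

    def test_goal_ids_are_recorded_per_trial(self):
        task = dynamic_task()
        student = Student(StudentSpec(
            regressors=task.regressors, initial_weights={"orient": 50.0},
            hyper=Hyper(alpha=1e-9), choice_policy="threshold"))
        goal = GoalSpec({"orient": 1.0},
                        rule=lambda s: 1 if s["orient"] > 0 else -1,
                        criterion=Criterion(window=500, threshold=0.8),
                        test_block=Criterion(window=100, threshold=0.8),
                        name="g")
        r = run_goal_schedule(task, [goal], "random", student, seed=0,
                              budget_per_goal=1000)
        assert {t.protocol_id for t in r.log} == {"g:learning", "g:testing"}

    def test_budget_shortfall_is_flagged_not_raised(self):
        task = afc2_task()
        student = Student(StudentSpec(hyper=Hyper(alpha=1e-9)))  # never learns
        goal = GoalSpec({"S0": 1.0}, criterion=Criterion(window=50,
                                                         threshold=0.9),
                        name="hard")
        r = run_goal_schedule(task, [goal], "random", student, seed=0,
                              budget_per_goal=200)
        assert r.status == "budget_exhausted"
        assert r.n_trials == 200


class TestPresets:
    def test_working_memory_preset_matches_the_deployed_configuration(self):
        cfg = preset_configs()["working_memory"]
        assert len(cfg.task.repertoire) == 20
        assert cfg.hyper == Hyper(alpha=0.01, eta=0.0, gamma=0.03, lam=0.0)
        assert cfg.task.regressors == ("bias", "S0", "T0", "S1", "A1", "R1",
                                       "WSLS")
        ranks = [cfg.task.difficulty_rank(s) for s in cfg.task.repertoire]
        assert sorted(ranks).count(4) == 8  # eight hardest trial types

    def test_2afc_preset_uses_the_six_regressor_model(self):
        cfg = preset_configs()["2afc"]
        assert cfg.task.regressors == ("bias", "S0", "S1", "A1", "R1", "WSLS")
        assert cfg.hyper == Hyper(alpha=0.1, eta=0.9, gamma=1.0, lam=0.1)

    def test_simulation_preset_initializes_the_noisy_student(self):
        cfg = preset_configs()["simulation"]
        student = cfg.make_student()
        assert student.state.weight("bias") == 2.0
        assert student.state.weight("S1") == -2.0

    def test_dynamic_preset_schedules_three_rules(self):
        cfg = preset_configs()["dynamic"]
        assert [g.name for g in cfg.goals] == ["orientation", "frequency",
                                               "frequency_reversed"]
        stim = {"freq": 1.0, "orient": -1.0}
        assert cfg.goals[1].rule(stim) == 1
        assert cfg.goals[2].rule(stim) == -1
        assert all(g.label_mode == "free" for g in cfg.goals)

    def test_wm_rule_and_difficulty_grading(self):
        task = working_memory_task()
        assert task.rule({"S0": -1.0, "T0": 1.0}) == 1
        assert task.rule({"S0": 0.5, "T0": 0.0}) == -1
        assert task.difficulty_rank({"S0": 0.0, "T0": 0.5}) == 4
        assert task.difficulty_rank({"S0": -1.0, "T0": 1.0}) == 1
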