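import math

import numpy as np
import pytest

from trialteacher.teacher import (CandidateTrial,
                                  antibias_next_direction, difficulty_T1,
                                  make_policy, p_left, random_next,
                                  select_next_trial, teaching_objective,
                                  usefulness_T2)
from trialteacher.trial_data import FeatureVector, TrialLog

from conftest import make_log, make_trial

NAMES = ("bias", "S0")


def fv(*values, names=NAMES):
    return FeatureVector(tuple(names), np.array(values, dtype=float))


def cand(values, y, names=NAMES):
    return CandidateTrial({"S0": values[1]}, y, fv(*values, names=names))


class TestObjectiveTerms:
    def test_t1_is_half_at_zero_weights(self):
        assert difficulty_T1(np.zeros(2), fv(1.0, -1.0), 1) == 0.5
        assert difficulty_T1(np.zeros(2), fv(1.0, -1.0), -1) == 0.5

    @pytest.mark.parametrize("margin,expected", [(4.0, 0.0180), (-4.0, 0.9820)])
    def test_t1_follows_the_margin(self, margin, expected):
        # weights (0, margin*y) with x_S0 = 1 give y<w,x> = margin
        w = np.array([0.0, margin])
        assert difficulty_T1(w, fv(0.0, 1.0), 1) == pytest.approx(expected, abs=5e-4)

    def test_t1_label_complement_sums_to_one(self, rng):
        for _ in range(20):
            w, x = rng.normal(size=2), fv(*rng.normal(size=2))
            assert difficulty_T1(w, x, 1) + difficulty_T1(w, x, -1) == \
                pytest.approx(1.0, rel=1e-12)

    def test_t2_vanishes_at_the_goal_and_at_zero_residual(self):
        w = np.array([1.0, 2.0])
        assert usefulness_T2(w, w, fv(1.0, 1.0), 1) == 0.0
        w_star = np.zeros(2)
        x = fv(0.0, 1.0)  # <w, x> = 1 = y: zero residual
        assert usefulness_T2(np.array([0.0, 1.0]), w_star, x, 1) == 0.0

    def test_t2_hand_arithmetic(self):
        # w=(2,0), w*=(0,1), x=(1,1), y=+1: residual = 2-1 = 1, g = (1,1),
        # T2 = <(2,-1), (1,1)> = 1
        assert usefulness_T2(np.array([2.0, 0.0]), np.array([0.0, 1.0]),
                             fv(1.0, 1.0), 1) == pytest.approx(1.0)


class TestSelection:
    def test_singleton_repertoire_is_returned(self, rng):
        only = cand([1.0, 1.0], 1)
        assert select_next_trial(np.zeros(2), np.ones(2), [only], 1.0, rng) is only

    def test_empty_repertoire_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            select_next_trial(np.zeros(2), np.ones(2), [], 1.0, rng)

    def test_argmin_matches_exhaustive_re_evaluation(self, rng):
        for _ in range(25):
            w, w_star = rng.normal(size=3), rng.normal(size=3)
            gamma = float(rng.uniform(0.05, 2.0))
            cands = [cand(rng.uniform(-1, 1, size=3), int(rng.choice([-1, 1])),
                          names=("bias", "S0", "S1"))
                     for _ in range(8)]
            # independent scoring from the closed forms
            scores = []
            for c in cands:
                z = float(np.dot(w, c.x.values))
                t1 = 1.0 / (1.0 + math.exp(c.y * z))
                g = [(z - c.y) * xi for xi in c.x.values]
                t2 = sum((wi - si) * gi for wi, si, gi in zip(w, w_star, g))
                scores.append(gamma ** 2 * t1 - 2 * gamma * t2)
            got = select_next_trial(w, w_star, cands, gamma, rng)
            assert teaching_objective(w, w_star, got.x, got.y, gamma) == \
                pytest.approx(min(scores), rel=1e-10)

    def test_selection_invariant_to_candidate_ordering(self, rng):
        w, w_star = rng.normal(size=2), rng.normal(size=2)
        cands = [cand(rng.uniform(-1, 1, size=2), int(rng.choice([-1, 1])))
                 for _ in range(6)]
        a = select_next_trial(w, w_star, cands, 0.5, np.random.default_rng(0))
        b = select_next_trial(w, w_star, cands[::-1], 0.5, np.random.default_rng(0))
        assert a.y == b.y and a.stimulus == b.stimulus

    def test_at_the_goal_selection_minimizes_difficulty(self, rng):
        # w == w* makes T2 vanish; the easiest candidate wins
        w = np.array([0.0, 1.5])
        cands = [cand([1.0, s], int(np.sign(s) or 1)) for s in (-1.0, -0.2, 1.0)]
        got = select_next_trial(w, w.copy(), cands, 1.0, rng)
        t1s = [difficulty_T1(w, c.x, c.y) for c in cands]
        assert difficulty_T1(w, got.x, got.y) == pytest.approx(min(t1s))


class TestDecompositionIdentity:
    def test_plain_step_distance_change_is_quadratic_minus_usefulness(self, rng):
        # ||w' - w*||^2 - ||w - w*||^2 == gamma^2 ||g||^2 - 2 gamma T2 exactly
        # for the plain-step learner w' = w - gamma g, g = (<w,x> - y) x
        for _ in range(100):
            k = int(rng.integers(2, 6))
            w, w_star = rng.normal(size=k), rng.normal(size=k)
            xv = rng.uniform(-1, 1, size=k)
            y = int(rng.choice([-1, 1]))
            gamma = float(rng.uniform(0.01, 2.0))
            x = FeatureVector(tuple(f"r{i}" for i in range(k)), xv)
            g = (float(w @ xv) - y) * xv
            w_next = w - gamma * g
            lhs = float(np.sum((w_next - w_star) ** 2) - np.sum((w - w_star) ** 2))
            rhs = gamma ** 2 * float(g @ g) - \
                2 * gamma * usefulness_T2(w, w_star, x, y)
            assert lhs == pytest.approx(rhs, rel=1e-10, abs=1e-12)

    def test_gradient_norm_t1_variant_reproduces_the_identity(self, rng):
        w, w_star = rng.normal(size=2), rng.normal(size=2)
        xv = rng.uniform(-1, 1, size=2)
        y, gamma = 1, 0.7
        x = fv(*xv)
        g = (float(w @ xv) - y) * xv
        w_next = w - gamma * g
        lhs = float(np.sum((w_next - w_star) ** 2) - np.sum((w - w_star) ** 2))
        assert teaching_objective(w, w_star, x, y, gamma,
                                  t1_form="gradient_norm") == \
            pytest.approx(lhs, rel=1e-10)


class TestAntibias:
    def test_three_same_side_rewards_force_a_switch(self):
        log = make_log([("right", dict(correct=True))] * 3)
        assert antibias_next_direction(log, rng=np.random.default_rng(0)) == "left"

    def test_failure_streak_overrides_the_switch_rule(self):
        # last three trials are left-type errors AND three consecutive
        # left-reward-direction trials: the failure streak wins -> left again
        log = make_log([("left", dict(correct=False))] * 3)
        assert antibias_next_direction(log, rng=np.random.default_rng(0)) == "left"

    def test_no_response_counts_toward_the_failure_streak(self):
        log = make_log([("left", dict(correct=False)), ("left", dict()),
                        ("left", dict(correct=False))])
        assert antibias_next_direction(log, rng=np.random.default_rng(0)) == "left"

    def test_symmetric_history_gives_even_odds(self):
        specs = ([("left", dict(correct=True)), ("right", dict(correct=True)),
                  ("left", dict(correct=False)), ("right", dict(correct=False))] * 5)
        log = make_log(specs)
        assert p_left(log.trials) == 0.5

    def test_hand_computed_p_left_on_constructed_history(self):
        # 20 right-correct, 10 left-correct, 4 left-error, 16 right-error
        specs = ([("right", dict(correct=True))] * 20 +
                 [("left", dict(correct=True))] * 10 +
                 [("left", dict(correct=False))] * 4 +
                 [("right", dict(correct=False))] * 16)
        log = make_log(specs)
        assert p_left(log.trials, n=50) == pytest.approx(0.5 * (20 / 30 + 4 / 20))

    def test_empty_history_defaults_to_even_odds(self):
        assert p_left([]) == 0.5

    def test_no_four_run_of_same_direction_without_a_failure_streak(self, rng):
        # drive the scheduler closed-loop with an always-correct responder:
        # priority 1 can then never fire, so runs must cap at 3
        log = TrialLog()
        directions = []
        for i in range(400):
            d = antibias_next_direction(log, rng=rng)
            directions.append(d)
            log.append(make_trial(i, d, correct=True))
        run = 1
        for a, b in zip(directions, directions[1:]):
            run = run + 1 if a == b else 1
            assert run <= 3


class TestRandomPolicy:
    def test_uniform_frequencies_over_many_draws(self):
        rng = np.random.default_rng(5)
        cands = [cand([1.0, v], 1) for v in (-1.0, 0.0, 1.0)]
        counts = np.zeros(3)
        for _ in range(10_000):
            counts[cands.index(random_next(cands, rng))] += 1
        # multinomial 3-sigma band around n/3
        sigma = math.sqrt(10_000 * (1 / 3) * (2 / 3))
        assert np.all(np.abs(counts - 10_000 / 3) < 3 * sigma)

    def test_seeded_draws_repeat(self):
        cands = [cand([1.0, v], 1) for v in (-1.0, 1.0)]
        a = [random_next(cands, np.random.default_rng(9)).stimulus
             for _ in range(1)]
        b = [random_next(cands, np.random.default_rng(9)).stimulus
             for _ in range(1)]
        assert a == b

    def test_unknown_policy_name_rejected(self):
        with pytest.raises(ValueError, match="unknown policy"):
            make_policy("greedy")
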