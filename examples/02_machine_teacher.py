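"""Scoring candidate trials: difficulty T1, usefulness T2, and the argmin.

A surrogate model that has learned a rightward bias is steered toward a
stimulus-following goal.  The teacher scores both 2AFC trial types and picks
the one whose induced update best shortens the path to the goal — the
left-instructing trial, which counteracts the bias.
"""

import numpy as np

from trialteacher import GoalSpec, difficulty_T1, usefulness_T2, teaching_objective
from trialteacher.experiment import afc2_task, enumerate_candidates
from trialteacher.online_model import ModelState

task = afc2_task()
surrogate = ModelState.zeros(task.regressors,
                             {"bias": 1.0, "S0": 0.2})  # biased, barely rule-aware
goal = GoalSpec({"S0": 1.0}, name="frequency")
w_star = goal.target_vector(surrogate.names)

print("candidate      T1 (P(error))  T2 (usefulness)  gamma^2 T1 - 2 gamma T2")
for cand in enumerate_candidates(task, goal, prev=None):
    t1 = difficulty_T1(surrogate, cand.x, cand.y)
    t2 = usefulness_T2(surrogate, w_star, cand.x, cand.y)
    obj = teaching_objective(surrogate, w_star, cand.x, cand.y, gamma=1.0)
    side = "left " if cand.y < 0 else "right"
    print(f"{side} trial    {t1:10.3f}   {t2:14.3f}   {obj:18.3f}")

print("\nThe left trial is harder for this rightward-biased model (higher T1)")
print("but far more useful (higher T2): its expected update simultaneously")
print("cuts the bias and grows the stimulus weight, so the teacher selects it.")
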