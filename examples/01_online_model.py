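"""Trial-by-trial online decision model: weights chase a consistent rule.

Builds a six-regressor online learner and feeds it the same left-instructing
trial repeatedly.  The momentum/L1 update drives the decision variable
<w, x> toward the -1 (left) choice label.
"""

import numpy as np

from trialteacher import Hyper, ModelState, predict_p_right, update
from trialteacher.trial_data import DEFAULT_REGRESSORS, FeatureVector

hyper = Hyper(alpha=0.1, eta=0.9, lam=0.1)
state = ModelState.zeros(DEFAULT_REGRESSORS)
x = FeatureVector(DEFAULT_REGRESSORS, np.array([1.0, -1.0, 0.0, 0.0, 0.0, 0.0]))

print("trial   <w,x>    P(right)   w_S0")
for t in range(30):
    state = update(state, x, -1, hyper)
    if t % 5 == 4:
        z = x.dot(state.w)
        print(f"{t + 1:5d}  {z:+.3f}    {predict_p_right(state, x):.3f}    "
              f"{state.weight('S0'):+.3f}")

print("\nThe decision variable approaches the -1 label, so P(right) falls.")
print("The stimulus weight grows positive: with S0 = -1 on left trials, a")
print("positive weight is exactly the rule-following solution.")
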