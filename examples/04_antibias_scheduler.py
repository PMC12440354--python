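"""The three-priority anti-bias scheduler on hand-built histories.

Shows each priority firing: repeat after a failure streak, switch after
three same-side rewards, and the history-weighted left probability.
"""

import numpy as np

from trialteacher import antibias_next_direction, p_left
from trialteacher.trial_data import TrialRecord


def rec(i, side, outcome):
    choice = {"correct": side,
              "error": "left" if side == "right" else "right",
              "no_response": "none"}[outcome]
    return TrialRecord(i, {"S0": 1.0 if side == "right" else -1.0}, side,
                       choice, outcome == "correct", outcome)


rng = np.random.default_rng(0)

streak = [rec(i, "left", "error") for i in range(3)]
print("three straight left-side errors      ->",
      antibias_next_direction(streak, rng=rng), "(repeat: highest priority)")

rewards = [rec(i, "right", "correct") for i in range(3)]
print("three straight right-side rewards    ->",
      antibias_next_direction(rewards, rng=rng), "(switch: second priority)")

history = ([rec(i, "right", "correct") for i in range(20)] +
           [rec(20 + i, "left", "correct") for i in range(10)] +
           [rec(30 + i, "left", "error") for i in range(4)] +
           [rec(34 + i, "right", "error") for i in range(16)])
print(f"50-trial mixed history: P(left trial) = {p_left(history):.4f}")
print("  = 1/2 (20/(20+10) + 4/(4+16)): the mouse does better on right")
print("  trials and errs more on right trials too, so left is undersampled")
print("  relative to chance here (P_left < 0.5).")
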