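"""Psychophysical kernel of a synthetic evidence-accumulation agent.

The agent weighs events in the first 12 of 25 40-ms bins twice as heavily
as late events.  One hundred paired GLM fits on 10% subsamples (real vs
within-trial-shuffled bins) recover the early-heavy kernel; the shuffled
baseline is flat because shuffling destroys temporal order.
"""

import numpy as np

from trialteacher import generate_event_log, psychophysical_kernel

true_kernel = np.r_[np.full(12, 0.5), np.full(13, 0.25)]
log = generate_event_log(true_kernel, 2500, seed=8)
kf = psychophysical_kernel(log, seed=8)

early, late = kf.kernel[:12].mean(), kf.kernel[13:].mean()
print(f"recovered kernel: early bins {early:.2f}, late bins {late:.2f} "
      f"(true ratio 2:1)")
print(f"shuffled baseline: mean {kf.baseline.mean():.2f}, "
      f"spread {kf.baseline.std(ddof=1):.2f} - no early/late structure")
print("\nbin :", "  ".join(f"{v:5.2f}" for v in kf.kernel[::4]))
print("base:", "  ".join(f"{v:5.2f}" for v in kf.baseline[::4]))
print("\nEarly bins carry roughly twice the weight of late bins, matching the")
print("agent; the baseline retains only the temporally uniform count signal.")
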