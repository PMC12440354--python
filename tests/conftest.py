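import numpy as np
import pytest

from trialteacher.trial_data import (CORRECT, ERROR, NO_RESPONSE, TrialLog,
                                     TrialRecord)


def make_trial(index, side, *, choice=None, correct=None, stim=None,
               protocol="p0"):
    """Build a consistent TrialRecord from a side and an outcome flag.

    ``choice=None`` with ``correct=None`` makes a no-response trial;
    otherwise ``correct`` decides whether the choice matches ``side``.
    """
    if choice is None and correct is None:
        return TrialRecord(index, stim or {"S0": 1.0 if side == "right" else -1.0},
                           side, "none", False, NO_RESPONSE, protocol)
    if choice is None:
        other = "left" if side == "right" else "right"
        choice = side if correct else other
    ok = choice == side
    return TrialRecord(index, stim or {"S0": 1.0 if side == "right" else -1.0},
                       side, choice, ok, CORRECT if ok else ERROR, protocol)


def make_log(specs, metadata=None):
    """specs: iterable of (side, kwargs) applied through make_trial."""
    log = TrialLog(metadata=metadata or {})
    for i, (side, kw) in enumerate(specs):
        log.append(make_trial(i, side, **kw))
    return log


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ten_trial_log():
    specs = [
        ("left", dict(correct=True)),
        ("right", dict(correct=False)),
        ("right", dict()),                      # no-response
        ("left", dict(correct=True)),
        ("right", dict(correct=True)),
        ("left", dict(correct=False)),
        ("left", dict(correct=True, stim={"S0": -0.5})),
        ("right", dict(correct=True, stim={"S0": 0.5})),
        ("left", dict()),                       # no-response
        ("right", dict(correct=True)),
    ]
    return make_log(specs, metadata={"task": "unit-fixture", "seed": 7})
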