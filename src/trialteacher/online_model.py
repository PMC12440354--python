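"""Trial-by-trial online linear decision model.

The decision variable is z = <w, x> over the named regressors of a
:class:`~trialteacher.trial_data.FeatureVector`; P(right) = sigmoid(z).
Weights are updated after every choice trial by a momentum-smoothed,
L1-regularized gradient step:

    m_t = (1 - eta) * (<w, x> - y) * x + eta * m_{t-1},        m_0 = 0
    w_{t+1} = w_t - alpha * (m_t / (1 - eta^t) + lam * sign(w_t))

with the choice label y in {-1, +1} (right = +1).  The residual (<w,x> - y)
is a squared-error gradient on the raw decision variable; a cross-entropy
variant ((sigmoid(z) - (y+1)/2) * x) is available via ``Hyper.gradient``.
The 1/(1 - eta^t) factor is the standard momentum bias correction: under a
constant gradient g the corrected momentum equals g exactly at every t.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .trial_data import FeatureVector

RESIDUAL = "residual"
LOGISTIC = "logistic"


@dataclass(frozen=True)
class Hyper:
    """Learner hyperparameters.

    alpha    learning rate (> 0)
    eta      momentum smoothing in [0, 1)
    gamma    hypothesized learning rate of the subject, used by the teacher
    lam      L1 penalty strength (>= 0)
    gradient "residual" (squared-error form, the default) or "logistic"
    """

    alpha: float
    eta: float = 0.0
    gamma: float = 1.0
    lam: float = 0.0
    gradient: str = RESIDUAL

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not 0 <= self.eta < 1:
            raise ValueError(
                f"eta must lie in [0, 1); eta={self.eta} degenerates the "
                "1/(1 - eta^t) bias correction")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if self.gradient not in (RESIDUAL, LOGISTIC):
            raise ValueError(f"unknown gradient form {self.gradient!r}")


@dataclass
class ModelState:
    """Weights, momentum accumulator and update counter of an online learner."""

    names: tuple[str, ...]
    w: np.ndarray
    m: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        if self.w.shape != (len(self.names),) or self.m.shape != self.w.shape:
            raise ValueError("w/m shape must match the regressor names")

    @classmethod
    def zeros(cls, names: Sequence[str],
              initial: dict[str, float] | None = None) -> "ModelState":
        """Fresh state; ``initial`` overrides individual starting weights."""
        names = tuple(names)
        w = np.zeros(len(names))
        if initial:
            for k, v in initial.items():
                if k not in names:
                    raise KeyError(f"initial weight for unknown regressor {k!r}")
                w[names.index(k)] = v
        return cls(names, w, np.zeros(len(names)), 0)

    def weight(self, name: str) -> float:
        return float(self.w[self.names.index(name)])

    def copy(self) -> "ModelState":
        return ModelState(self.names, self.w.copy(), self.m.copy(), self.t)

    # -- checkpoint / resume -------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({"names": list(self.names), "w": self.w.tolist(),
                           "m": self.m.tolist(), "t": self.t})

    @classmethod
    def from_json(cls, text: str) -> "ModelState":
        d = json.loads(text)
        return cls(tuple(d["names"]), np.array(d["w"]), np.array(d["m"]),
                   int(d["t"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ModelState":
        return cls.from_json(Path(path).read_text())


def _check_names(names: tuple[str, ...], x: FeatureVector) -> None:
    if tuple(x.names) != tuple(names):
        raise ValueError(
            f"regressor mismatch: model has {names}, feature vector has {x.names}")


def sigmoid(z: float | np.ndarray):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


def predict_p_right(state_or_w: ModelState | np.ndarray, x: FeatureVector) -> float:
    """P(choice = right) = sigmoid(<w, x>)."""
    if isinstance(state_or_w, ModelState):
        _check_names(state_or_w.names, x)
        w = state_or_w.w
    else:
        w = np.asarray(state_or_w, dtype=float)
    return float(sigmoid(x.dot(w)))


def gradient(w: np.ndarray, x: np.ndarray, y: int, form: str = RESIDUAL) -> np.ndarray:
    """Per-trial loss gradient for label y in {-1, +1}."""
    z = float(np.dot(w, x))
    if form == RESIDUAL:
        return (z - y) * x
    if form == LOGISTIC:
        return (float(sigmoid(z)) - (y + 1) / 2.0) * x
    raise ValueError(f"unknown gradient form {form!r}")


def update(state: ModelState, x: FeatureVector, y: int, hyper: Hyper) -> ModelState:
    """One online update on a choice trial; returns a new state (t incremented)."""
    if y not in (-1, 1):
        raise ValueError(f"choice label must be -1 or +1, got {y}")
    _check_names(state.names, x)
    t = state.t + 1
    g = gradient(state.w, x.values, y, hyper.gradient)
    m = (1.0 - hyper.eta) * g + hyper.eta * state.m
    m_hat = m / (1.0 - hyper.eta ** t)
    w = state.w - hyper.alpha * (m_hat + hyper.lam * np.sign(state.w))
    return ModelState(state.names, w, m, t)
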