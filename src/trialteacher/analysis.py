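"""Offline behavioral-strategy analysis.

The pipeline mirrors how long home-cage training logs are analyzed:

1.  drop habituation-protocol and no-response trials, concatenate the rest in
    chronological order;
2.  slide 500-trial windows with a 100-trial step (shorter tails discarded)
    and fit an unpenalized logistic GLM of choice on the behavioral
    regressors in each window, assuming a locally consistent strategy;
3.  score each window by 10-fold cross-validated prediction accuracy at the
    0.5 threshold, and each regressor by a corrected resampled t-test over a
    10x10 cross-validation model comparison (the regressor is zeroed at test
    time in the partial model);
4.  quantify side preference with performance/trial-type bias indices;
5.  for event-train (evidence accumulation) sessions, estimate the
    psychophysical kernel from 100 pairs of subsampled GLM fits, the second
    of each pair trained on bin-shuffled trials as a temporal-structure-free
    baseline.

Cross-validation and significance fits minimize the cross-entropy by
full-batch gradient descent with early stopping on the held-out fold's loss
(stop after 5 consecutive epochs improving by less than 1e-4, cap 2000
epochs); reported window weights come from the same descent on all window
trials, stopped once the training loss stabilizes (an exact L-BFGS
maximum-likelihood fit is available as :func:`fit_logistic_full`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .trial_data import (DEFAULT_REGRESSORS, LEFT, RIGHT, TrialLog,
                         TrialRecord, design_matrix)

WINDOW_WIDTH = 500
WINDOW_STEP = 100

#: variance-inflation ratio of the corrected resampled t-test for 450/50 folds
TEST_TRAIN_RATIO = 50 / 450


# ---------------------------------------------------------------------------
# preprocessing and windowing


def preprocess(
    log: TrialLog | Sequence[TrialRecord],
    habituation_protocols: Iterable[str] = ("habituation",),
) -> list[TrialRecord]:
    """Choice-trial sequence: habituation and no-response trials removed,
    chronological order preserved."""
    trials = log.trials if isinstance(log, TrialLog) else list(log)
    drop = set(habituation_protocols)
    return [t for t in trials
            if t.protocol_id not in drop and t.is_choice_trial]


def sliding_windows(
    seq: Sequence,
    width: int = WINDOW_WIDTH,
    step: int = WINDOW_STEP,
) -> list[Sequence]:
    """Full-width trailing windows at starts 0, step, 2*step, ...; a shorter
    tail window is discarded."""
    if width < 1 or step < 1:
        raise ValueError("width and step must be >= 1")
    return [seq[s:s + width] for s in range(0, len(seq) - width + 1, step)]


# ---------------------------------------------------------------------------
# logistic fits

_MAX_EPOCHS = 2000
_PATIENCE = 5
_MIN_DELTA = 1e-4
_GD_LR = 0.5


def _nll(w: np.ndarray, X: np.ndarray, y01: np.ndarray) -> float:
    z = X @ w
    # log(1 + e^z) - y*z, numerically stabilized
    return float(np.mean(np.logaddexp(0.0, z) - y01 * z))


def _nll_grad(w: np.ndarray, X: np.ndarray, y01: np.ndarray) -> np.ndarray:
    p = 1.0 / (1.0 + np.exp(-(X @ w)))
    return X.T @ (p - y01) / len(y01)


def fit_logistic_full(X: np.ndarray, y01: np.ndarray,
                      max_iter: int = 500) -> np.ndarray:
    """Unpenalized cross-entropy minimization (L-BFGS) on all rows."""
    w0 = np.zeros(X.shape[1])
    res = optimize.minimize(_nll, w0, args=(X, y01), jac=_nll_grad,
                            method="L-BFGS-B",
                            options={"maxiter": max_iter})
    return res.x


def fit_logistic_stable(
    X: np.ndarray, y01: np.ndarray,
    lr: float = _GD_LR,
    max_epochs: int = _MAX_EPOCHS,
    patience: int = _PATIENCE,
    min_delta: float = _MIN_DELTA,
) -> np.ndarray:
    """Gradient descent from zero, stopped once the training loss stabilizes.

    Stopping when the per-epoch loss improvement stays below ``min_delta``
    for ``patience`` epochs leaves the mild implicit shrinkage of an
    unconverged descent path; with the near-collinear history regressors of
    binary 2AFC data (WSLS coincides with S1 there) this keeps nuisance
    weights bounded where the exact MLE is noisy.
    """
    w = np.zeros(X.shape[1])
    prev = np.inf
    stall = 0
    for _ in range(max_epochs):
        w = w - lr * _nll_grad(w, X, y01)
        loss = _nll(w, X, y01)
        if prev - loss < min_delta:
            stall += 1
            if stall >= patience:
                break
        else:
            stall = 0
        prev = loss
    return w


def fit_logistic_gd(
    X: np.ndarray, y01: np.ndarray,
    X_val: np.ndarray, y_val: np.ndarray,
    lr: float = _GD_LR,
    max_epochs: int = _MAX_EPOCHS,
    patience: int = _PATIENCE,
    min_delta: float = _MIN_DELTA,
) -> np.ndarray:
    """Full-batch gradient descent with early stopping on validation loss."""
    w = np.zeros(X.shape[1])
    best_loss = np.inf
    best_w = w
    stall = 0
    for _ in range(max_epochs):
        w = w - lr * _nll_grad(w, X, y01)
        loss = _nll(w, X_val, y_val)
        if loss < best_loss - min_delta:
            best_loss, best_w, stall = loss, w.copy(), 0
        else:
            stall += 1
            if stall >= patience:
                break
    return best_w


def _accuracy(w: np.ndarray, X: np.ndarray, y01: np.ndarray) -> float:
    """Prediction accuracy at the 0.5 probability threshold (z = 0)."""
    return float(np.mean((X @ w > 0) == (y01 > 0.5)))


def _fold_indices(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [fold for fold in np.array_split(perm, n_folds)]


# ---------------------------------------------------------------------------
# per-window fitting and significance


@dataclass
class WindowFit:
    """Fitted GLM for one analysis window."""

    start: int
    names: tuple[str, ...]
    beta: np.ndarray
    cv_accuracy: float
    p_values: dict[str, float] | None = None
    warning: bool = False

    @property
    def beta_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.beta)))

    @property
    def significant(self) -> dict[str, bool] | None:
        if self.p_values is None:
            return None
        return {k: p < 0.05 for k, p in self.p_values.items()}


def fit_window(
    window: Sequence[TrialRecord],
    regressors: Sequence[str] = DEFAULT_REGRESSORS,
    seed: int = 0,
    start: int = 0,
    n_folds: int = 10,
) -> WindowFit:
    """Window GLM: reported weights from a full-window fit, accuracy from CV.

    Each fold trains on the remaining trials by gradient descent, early
    stopped on the fold's held-out loss, and records held-out accuracy at
    the 0.5 threshold.  A single-class (constant-choice) window is returned
    with ``warning=True``.
    """
    X, y = design_matrix(window, regressors)
    y01 = (y > 0).astype(float)
    warning = len(np.unique(y01)) < 2
    beta = fit_logistic_stable(X, y01)
    rng = np.random.default_rng(seed)
    accs = []
    for test_idx in _fold_indices(len(window), n_folds, rng):
        train_mask = np.ones(len(window), bool)
        train_mask[test_idx] = False
        w = fit_logistic_gd(X[train_mask], y01[train_mask],
                            X[test_idx], y01[test_idx])
        accs.append(_accuracy(w, X[test_idx], y01[test_idx]))
    return WindowFit(start=start, names=tuple(regressors), beta=beta,
                     cv_accuracy=float(np.mean(accs)), warning=warning)


def corrected_resampled_ttest(
    diffs: np.ndarray,
    test_train_ratio: float = TEST_TRAIN_RATIO,
) -> tuple[float, float]:
    """One-sided corrected resampled t-test on repeated-CV differences.

    The naive resampled t-test treats the k fold differences as independent;
    overlapping training sets make that anti-conservative.  The corrected
    variant inflates the variance of the mean from 1/k to
    (1/k + n_test/n_train).  Returns (t, one-sided p for mean > 0); a
    zero-variance difference vector carries no evidence (p = 1).
    """
    d = np.asarray(diffs, dtype=float)
    k = d.size
    var = float(np.var(d, ddof=1))
    if var == 0.0:
        return 0.0, 1.0
    t = float(np.mean(d) / np.sqrt((1.0 / k + test_train_ratio) * var))
    return t, float(stats.t.sf(t, df=k - 1))


def window_significance(
    window: Sequence[TrialRecord],
    regressors: Sequence[str] = DEFAULT_REGRESSORS,
    seed: int = 0,
    n_reps: int = 10,
    n_folds: int = 10,
) -> dict[str, float]:
    """Per-regressor one-sided p-values from a 10x10 CV model comparison.

    ``n_reps * n_folds`` models are trained (fresh seeded fold partitions per
    repetition).  For each trained full model and each regressor, the partial
    model zeroes that regressor's column in the test rows only; the test is on
    the 100 full-minus-partial accuracy differences.
    """
    X, y = design_matrix(window, regressors)
    y01 = (y > 0).astype(float)
    rng = np.random.default_rng(seed)
    names = tuple(regressors)
    diffs: dict[str, list[float]] = {nm: [] for nm in names}
    for _ in range(n_reps):
        for test_idx in _fold_indices(len(window), n_folds, rng):
            train_mask = np.ones(len(window), bool)
            train_mask[test_idx] = False
            w = fit_logistic_gd(X[train_mask], y01[train_mask],
                                X[test_idx], y01[test_idx])
            acc_full = _accuracy(w, X[test_idx], y01[test_idx])
            for j, nm in enumerate(names):
                X_part = X[test_idx].copy()
                X_part[:, j] = 0.0
                diffs[nm].append(acc_full - _accuracy(w, X_part, y01[test_idx]))
    n_test = len(window) // n_folds
    ratio = n_test / (len(window) - n_test)
    return {nm: corrected_resampled_ttest(np.array(d), ratio)[1]
            for nm, d in diffs.items()}


def regressor_significance(
    window: Sequence[TrialRecord],
    regressor: str,
    regressors: Sequence[str] = DEFAULT_REGRESSORS,
    seed: int = 0,
) -> float:
    """p-value for one regressor's contribution in one window."""
    if regressor not in regressors:
        raise KeyError(f"{regressor!r} is not in the fitted set {tuple(regressors)}")
    return window_significance(window, regressors, seed)[regressor]


def analyze_log(
    log: TrialLog | Sequence[TrialRecord],
    regressors: Sequence[str] = DEFAULT_REGRESSORS,
    width: int = WINDOW_WIDTH,
    step: int = WINDOW_STEP,
    significance: bool = False,
    seed: int = 0,
    habituation_protocols: Iterable[str] = ("habituation",),
) -> list[WindowFit]:
    """Preprocess, window, and fit a whole log; optionally add p-values."""
    seq = preprocess(log, habituation_protocols)
    fits = []
    for w_i, window in enumerate(sliding_windows(seq, width, step)):
        fit = fit_window(window, regressors, seed=seed + w_i, start=w_i * step)
        if significance:
            fit.p_values = window_significance(window, regressors,
                                               seed=seed + w_i)
        fits.append(fit)
    return fits


def windows_frame(fits: Sequence[WindowFit]):
    """Tidy per-window table (start, beta:<name>..., cv_acc, p:<name>...)."""
    import pandas as pd

    rows = []
    for f in fits:
        row = {"start": f.start, "cv_acc": f.cv_accuracy, "warning": f.warning}
        row.update({f"beta:{nm}": v for nm, v in f.beta_dict.items()})
        if f.p_values:
            row.update({f"p:{nm}": v for nm, v in f.p_values.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bias metrics


def _side_perf(trials: Sequence[TrialRecord], side: str) -> float | None:
    of_side = [t for t in trials if t.correct_side == side and t.is_choice_trial]
    if not of_side:
        return None
    return float(np.mean([t.outcome == "correct" for t in of_side]))


def performance_bias(trials: Sequence[TrialRecord] | TrialLog) -> float:
    """|perf_L / (perf_L + perf_R) - 1/2|: 0 = balanced, 1/2 = one-sided.

    Undefined (NaN) when a trial type is absent or neither side has any
    correct response.
    """
    trials = trials.trials if isinstance(trials, TrialLog) else trials
    pl, pr = _side_perf(trials, LEFT), _side_perf(trials, RIGHT)
    if pl is None or pr is None or pl + pr == 0.0:
        return float("nan")
    return abs(pl / (pl + pr) - 0.5)


def trial_type_bias(trials: Sequence[TrialRecord] | TrialLog) -> float:
    """Same index on presented-trial-type counts instead of performance."""
    trials = trials.trials if isinstance(trials, TrialLog) else trials
    nl = sum(t.correct_side == LEFT for t in trials)
    nr = sum(t.correct_side == RIGHT for t in trials)
    if nl + nr == 0:
        return float("nan")
    return abs(nl / (nl + nr) - 0.5)


# ---------------------------------------------------------------------------
# psychophysical kernel


@dataclass
class KernelFit:
    """Per-time-bin evidence weights and their shuffle baseline."""

    bins: tuple[str, ...]
    kernel: np.ndarray
    baseline: np.ndarray
    n_pairs: int

    @property
    def n_bins(self) -> int:
        return len(self.bins)


def psychophysical_kernel(
    log: TrialLog | Sequence[TrialRecord],
    n_pairs: int = 100,
    subsample: float = 0.1,
    n_bins: int = 25,
    seed: int = 0,
) -> KernelFit:
    """Reverse-correlation kernel from paired subsampled GLM fits.

    Each of ``n_pairs`` pairs draws a fresh random ``subsample`` fraction of
    choice trials and fits two logistic models of choice on the per-bin event
    indicators: one on the real bin values and one with the bins shuffled
    within each trial (destroying temporal structure while preserving each
    trial's event count).  The kernel (baseline) is the mean of the real
    (shuffled) per-bin weights.
    """
    from sklearn.linear_model import LogisticRegression

    trials = preprocess(log)
    bin_names = sorted(d for t in trials[:1] for d in t.stimulus
                       if d.startswith("bin"))
    if len(bin_names) < n_bins:
        raise ValueError(
            f"need {n_bins} event bins, found {len(bin_names)}")
    bin_names = bin_names[:n_bins]
    E = np.array([[t.stimulus[b] for b in bin_names] for t in trials])
    y = np.array([1 if t.choice == RIGHT else 0 for t in trials])
    rng = np.random.default_rng(seed)
    n_sub = max(int(round(subsample * len(trials))), n_bins + 1)

    def _fit(Xs, ys):
        # effectively unpenalized; a finite C keeps separable subsamples finite
        clf = LogisticRegression(C=1e4, max_iter=2000)
        clf.fit(Xs, ys)
        return clf.coef_[0]

    real, shuf = [], []
    for _ in range(n_pairs):
        for _try in range(100):
            idx = rng.choice(len(trials), size=n_sub, replace=False)
            if len(np.unique(y[idx])) == 2:
                break
        Xs = E[idx]
        real.append(_fit(Xs, y[idx]))
        X_shuf = np.array([row[rng.permutation(n_bins)] for row in Xs])
        shuf.append(_fit(X_shuf, y[idx]))
    return KernelFit(tuple(bin_names), np.mean(real, axis=0),
                     np.mean(shuf, axis=0), n_pairs)
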