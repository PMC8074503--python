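"""Binary C-SVM on precomputed kernels, with grid search and the
iterative predicted-label feature augmentation.

The decision function is f(x) = sgn{ sum_i y_i a_i K(x_i, x) + b } with the
box constraint 0 <= a_i <= C and sum_i a_i y_i = 0.  Class labels are
+1 = circadian (CRG) and -1 = non-circadian.  The quadratic program is
delegated to scikit-learn's C-SVC solver operating on this package's own
Gram matrices; features are z-scored with train-fitted statistics before any
kernel evaluation, and probabilities come from a Platt-style sigmoid fitted
on training decision values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .kernels import KernelSpec, gram

logger = logging.getLogger(__name__)

#: Power-of-two grid used for both gamma and C: 2^-6 .. 2^6.
GRID_POWERS = tuple(range(-6, 7))


@dataclass(frozen=True)
class PlattCalibrator:
    """Monotone sigmoid map from decision value to P(class = +1)."""

    coef: float
    intercept: float

    def __call__(self, decision: np.ndarray) -> np.ndarray:
        z = self.coef * np.asarray(decision, dtype=float) + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


def _fit_platt(decisions: np.ndarray, y: np.ndarray) -> PlattCalibrator:
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
    lr.fit(decisions.reshape(-1, 1), y)
    coef = float(lr.coef_[0, 0])
    intercept = float(lr.intercept_[0])
    if coef < 0:  # keep probability monotone increasing in the decision value
        logger.warning("Platt calibration produced a decreasing map; flattening")
        coef, intercept = 0.0, 0.0
    return PlattCalibrator(coef=coef, intercept=intercept)


@dataclass
class SVMModel:
    """A fitted kernel C-SVM plus its scaler and probability calibrator."""

    spec: KernelSpec
    C: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    support_vectors: np.ndarray  # scaled feature rows x_i
    dual_coefs: np.ndarray  # a_i * y_i
    bias: float
    calibrator: PlattCalibrator
    n_features: int = 0

    def _scale(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        return (X - self.scaler_mean) / self.scaler_scale

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        K = gram(self._scale(X), self.support_vectors, self.spec)
        return K @ self.dual_coefs + self.bias

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Labels in {-1, +1} (ties go to +1) and P(CRG) probabilities."""
        decision = self.decision_function(X)
        labels = np.where(decision >= 0, 1, -1)
        return labels, self.calibrator(decision)


def fit(X: np.ndarray, y: np.ndarray, spec: KernelSpec, C: float = 1.0) -> SVMModel:
    """Fit the C-SVM on labelled feature rows.

    Standardization statistics are computed from these rows only, so fitting
    on a training fold never sees test data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) != {-1, 1}:
        raise ValueError("y must contain both classes, labelled +1 and -1")
    if C <= 0:
        raise ValueError("C must be positive")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # constant feature: leave centred at zero
    Xs = (X - mean) / scale
    resolved = replace(spec, gamma=spec.resolve_gamma(X.shape[1]))
    K = gram(Xs, Xs, resolved)
    svc = SVC(C=C, kernel="precomputed")
    svc.fit(K, y)
    if svc.fit_status_ != 0:  # pragma: no cover - solver failure surface
        raise RuntimeError("C-SVC solver did not converge")
    support = svc.support_
    model = SVMModel(
        spec=resolved,
        C=C,
        scaler_mean=mean,
        scaler_scale=scale,
        support_vectors=Xs[support],
        dual_coefs=svc.dual_coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        calibrator=PlattCalibrator(1.0, 0.0),
        n_features=X.shape[1],
    )
    model.calibrator = _fit_platt(model.decision_function(X), y)
    return model


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """(TPR + TNR) / 2; reduces to the defined rate if one class is absent."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    rates = []
    for cls in (1, -1):
        mask = y_true == cls
        if mask.any():
            rates.append(float((y_pred[mask] == cls).mean()))
    return float(np.mean(rates))


def _oof_predictions(
    X: np.ndarray,
    y: np.ndarray,
    spec: KernelSpec,
    C: float,
    folds: int,
    seed: int,
) -> np.ndarray:
    """Out-of-fold predicted labels from stratified k-fold CV."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.zeros(len(y), dtype=int)
    for train_idx, test_idx in skf.split(X, y):
        model = fit(X[train_idx], y[train_idx], spec, C)
        oof[test_idx], _ = model.predict(X[test_idx])
    return oof


@dataclass(frozen=True)
class GridSearchResult:
    gamma: float | None
    C: float
    score: float
    table: list[tuple[float | None, float, float]]  # (gamma, C, score)


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    kernel: str,
    folds: int = 5,
    seed: int = 0,
    powers: Sequence[int] = GRID_POWERS,
) -> GridSearchResult:
    """Power-of-two grid search over (gamma, C) by mean CV balanced accuracy.

    The grid is 2^-6 .. 2^6 for both parameters (C only for the linear
    kernel).  Ties break toward smaller C, then smaller gamma, by evaluating
    candidates in that order and keeping strictly better scores only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    c_values = [2.0**p for p in powers]
    if kernel == "linear":
        gammas: list[float | None] = [None]
    else:
        gammas = [2.0**p for p in powers]
    best: tuple[float | None, float, float] | None = None
    table = []
    for C in c_values:
        for g in gammas:
            spec = KernelSpec(name=kernel, gamma=g)
            oof = _oof_predictions(X, y, spec, C, folds, seed)
            score = balanced_accuracy(y, oof)
            table.append((g, C, score))
            if best is None or score > best[2]:
                best = (g, C, score)
    assert best is not None
    return GridSearchResult(gamma=best[0], C=best[1], score=best[2], table=table)


@dataclass
class IterativeResult:
    """Outcome of the predicted-label feature augmentation loop."""

    model: SVMModel
    trace: np.ndarray  # CV balanced accuracy per iteration (index 0 = base)
    best_iteration: int
    n_features_final: int


def iterate_label_feature(
    X: np.ndarray,
    y: np.ndarray,
    spec: KernelSpec,
    C: float = 1.0,
    max_iter: int = 50,
    patience: int = 5,
    folds: int = 5,
    seed: int = 0,
) -> IterativeResult:
    """Iteratively append the out-of-fold predicted label as a new feature.

    Each iteration computes stratified out-of-fold predictions with the
    current feature set, records the CV balanced accuracy, then appends the
    prediction column (+/-1 values) and refits.  Out-of-fold (rather than
    resubstitution) predictions are used so the appended feature carries no
    target leakage.  Stops after ``max_iter`` augmentations or once the
    accuracy has not improved for ``patience`` consecutive iterations; the
    returned model is refit on the feature set of the best iteration.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    X_cur = X
    oof = _oof_predictions(X, y, spec, C, folds, seed)
    trace = [balanced_accuracy(y, oof)]
    best_iter, best_score, best_X = 0, trace[0], X
    stall = 0
    for it in range(1, max_iter + 1):
        X_cur = np.hstack([X_cur, oof.reshape(-1, 1).astype(float)])
        oof = _oof_predictions(X_cur, y, spec, C, folds, seed + it)
        trace.append(balanced_accuracy(y, oof))
        if trace[-1] > best_score + 1e-12:
            best_iter, best_score, best_X = it, trace[-1], X_cur
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break
    model = fit(best_X, y, spec, C)
    return IterativeResult(
        model=model,
        trace=np.asarray(trace),
        best_iteration=best_iter,
        n_features_final=best_X.shape[1],
    )
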