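"""Partial least squares discriminant analysis (PLS-DA) on autoscaled data.

The classifier regresses centered one-hot class indicators on the
(autoscaled) metabolite matrix with NIPALS PLS2 and assigns each sample
to the class whose predicted indicator is largest.  Model quality is
summarised by R2 (fraction of indicator variance explained in fit), Q2
(1 - PRESS/TSS on held-out predictions under stratified K-fold CV),
cross-validated classification accuracy, and a label-permutation test
of that accuracy.  Variable importance in projection (VIP) scores rank
metabolites; by construction their squares average to one.

NIPALS is implemented directly (deflation of both blocks per component)
so that weights, scores, loadings and the per-component explained
indicator variance needed by the VIP formula are all first-class
outputs; an independent PLS implementation serves as a cross-check in
the test suite, not as the backend.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import IntensityMatrix
from .errors import DegenerateDataError

logger = logging.getLogger(__name__)

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 500


# ---------------------------------------------------------------------------
# autoscaling
# ---------------------------------------------------------------------------


def autoscale(matrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Center each metabolite to mean 0 and scale to unit (n-1) sd.

    Accepts an :class:`IntensityMatrix` or a plain DataFrame; returns the
    scaled frame plus a (metabolite x {mean, sd}) statistics frame.
    """
    frame = matrix.data if isinstance(matrix, IntensityMatrix) else matrix
    if len(frame) < 2:
        raise DegenerateDataError("autoscaling needs >= 2 samples")
    mean = frame.mean(axis=0)
    sd = frame.std(axis=0, ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise DegenerateDataError(
            f"constant-valued metabolite(s): {', '.join(map(str, constant))}"
        )
    scaled = (frame - mean) / sd
    stats = pd.DataFrame({"mean": mean, "sd": sd})
    return scaled, stats


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


def _as_array(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def _one_hot(y) -> tuple[np.ndarray, list]:
    labels = np.asarray(y)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise DegenerateDataError("PLS-DA needs >= 2 classes")
    Y = np.zeros((len(labels), len(classes)))
    for k, cls in enumerate(classes):
        Y[labels == cls, k] = 1.0
    return Y, classes


@dataclass
class PLSDAModel:
    n_components: int
    classes: list
    feature_names: list[str]
    x_mean: np.ndarray
    y_mean: np.ndarray
    scores: np.ndarray        # n x A
    weights: np.ndarray       # p x A, unit-norm columns
    x_loadings: np.ndarray    # p x A
    y_loadings: np.ndarray    # c x A
    ssy: np.ndarray           # per-component explained indicator SS
    total_ssy: float
    coef: np.ndarray          # p x c regression coefficients
    r2: float

    def predict_indicator(self, X) -> np.ndarray:
        Xa, _ = _as_array(X)
        return (Xa - self.x_mean) @ self.coef + self.y_mean

    def predict(self, X) -> np.ndarray:
        yhat = self.predict_indicator(X)
        # argmax resolves ties toward the lowest class index
        return np.asarray(self.classes, dtype=object)[np.argmax(yhat, axis=1)]


def fit_plsda(X, y, n_components: int = 2) -> PLSDAModel:
    """Fit NIPALS PLS2 on one-hot class indicators (both blocks centered).

    Components beyond the rank of the centered X block are truncated
    with a warning.  Deterministic: no randomness enters the fit.
    """
    Xa, names = _as_array(X)
    Y, classes = _one_hot(y)
    x_mean = Xa.mean(axis=0)
    y_mean = Y.mean(axis=0)
    E = Xa - x_mean
    F = Y - y_mean
    total_ssy = float((F**2).sum())
    if total_ssy == 0:
        raise DegenerateDataError("class indicators have zero variance")
    max_rank = int(np.linalg.matrix_rank(E))
    A = min(n_components, max_rank)
    if A < n_components:
        warnings.warn(
            f"n_components={n_components} exceeds rank {max_rank}; truncated to {A}",
            stacklevel=2,
        )
    n, p = E.shape
    W = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    Q = np.zeros((Y.shape[1], A))
    ssy = np.zeros(A)
    for a in range(A):
        u = F[:, int(np.argmax(F.var(axis=0)))].copy()
        t_old = np.zeros(n)
        for _ in range(_NIPALS_MAX_ITER):
            w = E.T @ u
            norm = np.linalg.norm(w)
            if norm == 0:
                break
            w /= norm
            t = E @ w
            q = F.T @ t / (t @ t)
            u = F @ q / (q @ q)
            if np.linalg.norm(t - t_old) <= _NIPALS_TOL * np.linalg.norm(t):
                break
            t_old = t
        tt = float(t @ t)
        if tt == 0:
            A = a
            break
        p_vec = E.T @ t / tt
        E = E - np.outer(t, p_vec)
        F = F - np.outer(t, q)
        W[:, a], T[:, a], P[:, a], Q[:, a] = w, t, p_vec, q
        ssy[a] = tt * float(q @ q)
    W, T, P, Q, ssy = W[:, :A], T[:, :A], P[:, :A], Q[:, :A], ssy[:A]
    # regression coefficients in the original (centered) X space
    coef = W @ np.linalg.solve(P.T @ W, Q.T)
    r2 = float(ssy.sum() / total_ssy)
    return PLSDAModel(
        n_components=A,
        classes=classes,
        feature_names=names,
        x_mean=x_mean,
        y_mean=y_mean,
        scores=T,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        ssy=ssy,
        total_ssy=total_ssy,
        coef=coef,
        r2=r2,
    )


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VIPResult:
    scores: pd.Series          # per-metabolite VIP
    ranking: pd.Series = field(default=None)  # descending order

    def top(self, k: int) -> list[str]:
        return list(self.ranking.index[:k])


def vip_scores(model: PLSDAModel) -> VIPResult:
    """VIP_j = sqrt(p * sum_a w_ja^2 SSY_a / sum_a SSY_a)."""
    total = model.ssy.sum()
    if total == 0:
        raise DegenerateDataError("model explains no indicator variance")
    p = model.weights.shape[0]
    vip = np.sqrt(p * (model.weights**2 @ model.ssy) / total)
    series = pd.Series(vip, index=model.feature_names, name="vip")
    return VIPResult(scores=series, ranking=series.sort_values(ascending=False))


# ---------------------------------------------------------------------------
# cross-validation and permutation
# ---------------------------------------------------------------------------


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator):
    """Deterministic stratified fold assignment (round-robin after shuffle)."""
    assignment = np.zeros(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        assignment[idx] = np.arange(len(idx)) % folds
    return [(np.flatnonzero(assignment != f), np.flatnonzero(assignment == f)) for f in range(folds)]


def cross_validate(
    X, y, folds: int = 10, n_components: int = 2, seed: int = 0
) -> tuple[float, float]:
    """Stratified K-fold CV; returns (Q2, held-out classification accuracy).

    Q2 = 1 - PRESS/TSS over held-out one-hot indicators, with both
    residuals taken against the training-fold model/means.  Fold count
    is reduced (with a warning) when the smallest class has fewer
    members than requested folds.
    """
    Xa, _ = _as_array(X)
    labels = np.asarray(y)
    _, classes = _one_hot(labels)
    class_counts = {cls: int((labels == cls).sum()) for cls in classes}
    smallest = min(class_counts.values())
    if smallest < 2:
        raise DegenerateDataError("every class needs >= 2 samples for CV")
    if smallest < folds:
        warnings.warn(f"reducing folds from {folds} to {smallest}", stacklevel=2)
        folds = smallest
    rng = np.random.default_rng(seed)
    Y_full = np.zeros((len(labels), len(classes)))
    for k, cls in enumerate(classes):
        Y_full[labels == cls, k] = 1.0
    press = 0.0
    tss = 0.0
    correct = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank truncation inside small folds
        for train_idx, test_idx in _stratified_folds(labels, folds, rng):
            model = fit_plsda(Xa[train_idx], labels[train_idx], n_components)
            yhat = model.predict_indicator(Xa[test_idx])
            # align indicator columns in case a fold misses a class
            cols = [classes.index(c) for c in model.classes]
            resid = Y_full[np.ix_(test_idx, cols)] - yhat
            press += float((resid**2).sum())
            train_mean = Y_full[train_idx].mean(axis=0)
            tss += float(((Y_full[test_idx] - train_mean) ** 2).sum())
            correct += int((model.predict(Xa[test_idx]) == labels[test_idx]).sum())
    q2 = 1.0 - press / tss
    accuracy = correct / len(labels)
    return q2, accuracy


def permutation_test(
    X,
    y,
    n_perm: int = 1000,
    seed: int = 0,
    folds: int = 10,
    n_components: int = 2,
    statistic: str = "accuracy",
) -> tuple[float, float, np.ndarray]:
    """Label-permutation validation of the PLS-DA model.

    The statistic is the cross-validated classification accuracy (or Q2
    when ``statistic='q2'``); p = (1 + #{permuted >= observed}) /
    (n_perm + 1).  Returns (p, observed statistic, permuted statistics).
    """
    if n_perm < 1:
        raise DegenerateDataError("n_perm must be >= 1")
    which = {"accuracy": 1, "q2": 0}[statistic]
    labels = np.asarray(y)
    observed = cross_validate(X, labels, folds, n_components, seed)[which]
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = labels[rng.permutation(len(labels))]
        permuted[i] = cross_validate(X, shuffled, folds, n_components, seed)[which]
    p = (1.0 + float((permuted >= observed).sum())) / (n_perm + 1.0)
    return p, observed, permuted


def model_summary(model: PLSDAModel, q2: float, cv_accuracy: float, perm_p: float | None = None) -> dict:
    summary = {
        "n_components": model.n_components,
        "classes": [str(c) for c in model.classes],
        "r2": model.r2,
        "q2": q2,
        "cv_accuracy": cv_accuracy,
    }
    if perm_p is not None:
        summary["permutation_p"] = perm_p
    return summary
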