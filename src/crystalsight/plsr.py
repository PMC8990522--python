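"""SIMPLS partial least-squares regression for suspension-density
prediction.

The SIMPLS factors are extracted directly from the covariance vector
s = X^T y (de Jong's formulation): each weight is the deflated covariance
direction, scores are normalized, and s is deflated against the
orthonormal basis of the X-loadings (Gram-Schmidt). Inputs are
mean-centered only (no unit-variance scaling), so the weights remain
interpretable on the raw feature scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import GroupKFold, KFold
from sklearn.utils.validation import check_is_fitted

__all__ = ["SIMPLSRegression", "CVReport", "PredictionReport",
           "mean_center", "simpls_fit", "cross_validate", "evaluate",
           "scenario_split"]


def mean_center(X, y=None):
    """Column-center X (and y); returns centered arrays plus stored means."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    if y is None:
        return Xc, x_mean
    y = np.asarray(y, dtype=float).reshape(-1)
    y_mean = y.mean()
    return Xc, y - y_mean, x_mean, y_mean


def _simpls_core(Xc: np.ndarray, yc: np.ndarray, ncomp: int):
    """SIMPLS on centered data. Returns (R, P, q, T, achieved_ncomp)."""
    n, p = Xc.shape
    ncomp = int(min(ncomp, n - 1, p))
    R = np.zeros((p, ncomp))   # weights (applied to centered X)
    P = np.zeros((p, ncomp))   # X loadings
    q = np.zeros(ncomp)        # y loadings
    T = np.zeros((n, ncomp))   # orthonormal scores
    V = np.zeros((p, ncomp))   # orthonormal loading basis for deflation
    s = Xc.T @ yc
    s0 = np.linalg.norm(s)
    achieved = 0
    for a in range(ncomp):
        if np.linalg.norm(s) < 1e-12 * max(1.0, s0):
            break
        r = s.copy()
        t = Xc @ r
        nt = np.linalg.norm(t)
        if nt < 1e-14:
            break
        t /= nt
        r /= nt
        pload = Xc.T @ t
        q_a = float(yc @ t)
        v = pload.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pload)
        nv = np.linalg.norm(v)
        if nv < 1e-14:
            break
        v /= nv
        s = s - v * (v @ s)
        R[:, a], P[:, a], q[a], T[:, a], V[:, a] = r, pload, q_a, t, v
        achieved = a + 1
    return (R[:, :achieved], P[:, :achieved], q[:achieved],
            T[:, :achieved], achieved)


class SIMPLSRegression(RegressorMixin, BaseEstimator):
    """PLS1 regression via the SIMPLS algorithm.

    Parameters
    ----------
    n_components : int
        Number of latent variables. If the data support fewer (rank
        deficiency / zero residual covariance), extraction stops early
        and ``n_components_`` records the achieved count.

    Attributes
    ----------
    x_mean_, y_mean_ : centering vectors applied before projection.
    x_weights_ : (n_features, n_components_) SIMPLS weight matrix R.
    x_loadings_, y_loadings_ : P and q.
    coef_ : regression vector b = R q; prediction is
        y_mean_ + (x - x_mean_) . b.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        Xc, yc, x_mean, y_mean = mean_center(X, y)
        R, P, q, T, achieved = _simpls_core(Xc, yc, self.n_components)
        if achieved == 0:
            # no covariance at all: constant-mean model
            R = np.zeros((Xc.shape[1], 0))
            P, q, T = R.copy(), np.zeros(0), np.zeros((Xc.shape[0], 0))
        self.x_mean_, self.y_mean_ = x_mean, y_mean
        self.x_weights_, self.x_loadings_, self.y_loadings_ = R, P, q
        self.scores_ = T
        self.n_components_ = achieved
        self.coef_ = R @ q
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.y_mean_ + (X - self.x_mean_) @ self.coef_

    def coef_path(self) -> np.ndarray:
        """Regression vectors for every truncation 1..n_components_
        (columns), allowing all CV candidate counts from one fit."""
        check_is_fitted(self, "coef_")
        R, q = self.x_weights_, self.y_loadings_
        return np.cumsum(R * q[None, :], axis=1)


def simpls_fit(X, y, ncomp: int) -> SIMPLSRegression:
    return SIMPLSRegression(n_components=ncomp).fit(X, y)


@dataclass(frozen=True)
class CVReport:
    msecv: dict                 # ncomp -> mean squared held-out error
    chosen_ncomp: int
    folds: int
    seed: int

    def __post_init__(self):
        best = min(self.msecv.values())
        if self.msecv[self.chosen_ncomp] != best:
            raise ValueError("chosen_ncomp must attain the minimum MSECV")


def cross_validate(X, y, folds: int = 10, ncomp_max: int = 10,
                   seed: int = 0, groups=None) -> CVReport:
    """Seeded K-fold MSECV curve and latent-variable choice.

    With ``groups`` the folds keep whole data sets together (group-level
    folds for set-to-set validation); otherwise observation-level folds
    with seeded shuffling. Ties in MSECV resolve to the smallest ncomp.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    if folds < 2 or folds > len(y):
        raise ValueError("folds must satisfy 2 <= folds <= n_samples")
    if groups is None:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(X)
    else:
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        rng = np.random.default_rng(seed)
        perm = {g: i for i, g in enumerate(rng.permutation(uniq))}
        shuffled = np.array([perm[g] for g in groups])
        splitter = GroupKFold(n_splits=folds)
        split = splitter.split(X, y, groups=shuffled)

    ncomps = None
    sq_sums = None
    n_held = 0
    for train_idx, test_idx in split:
        model = SIMPLSRegression(
            n_components=min(ncomp_max, len(train_idx) - 1, X.shape[1]))
        model.fit(X[train_idx], y[train_idx])
        path = model.coef_path()              # (p, achieved)
        achieved = path.shape[1]
        if ncomps is None:
            ncomps = achieved
            sq_sums = np.zeros(achieved)
        elif achieved < ncomps:               # truncated fold: warn via trim
            ncomps = achieved
            sq_sums = sq_sums[:achieved]
        Xt = X[test_idx] - model.x_mean_
        preds = model.y_mean_ + Xt @ path[:, :ncomps]
        resid = preds - y[test_idx, None]
        sq_sums[:ncomps] += (resid**2).sum(axis=0)
        n_held += len(test_idx)
    msecv = {a + 1: float(sq_sums[a] / n_held) for a in range(ncomps)}
    chosen = min(msecv, key=lambda a: (msecv[a], a))
    return CVReport(msecv=msecv, chosen_ncomp=chosen, folds=folds, seed=seed)


@dataclass(frozen=True)
class PredictionReport:
    q2: float
    residuals: np.ndarray
    mean_abs_residual: float


def evaluate(model: SIMPLSRegression, X, y) -> PredictionReport:
    """Goodness of prediction Q2 = 1 - SS_res / SS_tot with the *training*
    mean in the denominator; on the training data itself this is R2."""
    y = np.asarray(y, dtype=float).reshape(-1)
    yhat = model.predict(X)
    resid = y - yhat
    ss_tot = float(((y - model.y_mean_)**2).sum())
    if ss_tot == 0:
        raise ValueError("Q2 undefined: zero variance around the training mean")
    q2 = 1.0 - float((resid**2).sum()) / ss_tot
    return PredictionReport(q2=q2, residuals=resid,
                            mean_abs_residual=float(np.abs(resid).mean()))


def scenario_split(n_units: int, mode: str = "within_set", seed: int = 0,
                   train_frac: float = 0.85, n_test_sets: int = 2):
    """Randomized train/test partition of observation or data-set units.

    within_set: round(train_frac n) observations train, rest test (85:15).
    across_sets: ``n_test_sets`` whole data sets held out (10:2 for 12).
    Returns (train_indices, test_indices) into range(n_units).
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_units)
    if mode == "within_set":
        n_train = int(round(train_frac * n_units))
    elif mode == "across_sets":
        if n_units < 3:
            raise ValueError("across_sets needs >= 3 data sets")
        n_train = n_units - n_test_sets
    else:
        raise ValueError("mode must be 'within_set' or 'across_sets'")
    if not 0 < n_train < n_units:
        raise ValueError("degenerate split")
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])
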