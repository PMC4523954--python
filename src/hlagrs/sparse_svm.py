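"""L1/L2-penalized squared-hinge SVM via cyclic coordinate descent.

Model: for labels y in {-1, +1} and a standardized dosage matrix X,

    minimize  (1/n) sum_i max(0, 1 - y_i (b + x_i' w))^2
              + lambda1 ||w||_1 + lambda2 ||w||_2^2

with an unpenalized intercept b.  The squared hinge is differentiable
with a coordinate-wise gradient Lipschitz constant of (2/n) sum_i x_ij^2,
so each coordinate takes a proximal (soft-thresholded) majorization step
with curvature h_j = (2/n) sum_i x_ij^2 + 2 lambda2, which guarantees a
monotone nonincreasing objective across sweeps.  The L1 penalty drives
most weights exactly to zero; the solution path over a decreasing
lambda1 grid is warm-started.

Columns must be mean-imputed and standardized before fitting (see
:class:`Standardizer`); standardization constants are estimated on
training data only and frozen for test/validation scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "SVMModel",
    "PathResult",
    "Standardizer",
    "fit",
    "fit_path",
    "decision_scores",
    "lambda1_max",
    "objective",
]

_WEIGHT_EPS = 1e-12  # weights below this magnitude are treated as exact zeros


@dataclass
class SVMModel:
    intercept: float
    coef: np.ndarray  # dense weight vector on the standardized scale
    lambda1: float
    lambda2: float
    converged: bool
    objective: float
    n_sweeps: int

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coef))

    @property
    def weights(self) -> dict[int, float]:
        """Sparse mapping variant-index -> weight."""
        idx = np.flatnonzero(self.coef)
        return {int(j): float(self.coef[j]) for j in idx}


@dataclass
class PathResult:
    models: list[SVMModel]
    lambda1_grid: np.ndarray
    lambda2: float


class Standardizer:
    """Per-column mean imputation + mean-centering + unit-variance scaling.

    Fit on training data only; zero-variance columns get scale 1 (they
    standardize to all-zero and can never enter the model).
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.mean_ = np.nanmean(X, axis=0)
        self.mean_ = np.where(np.isnan(self.mean_), 0.0, self.mean_)
        imputed = np.where(np.isnan(X), self.mean_, X)
        sd = imputed.std(axis=0)
        sd[sd == 0] = 1.0
        self.scale_ = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Standardizer not fitted")
        X = np.asarray(X, dtype=float)
        imputed = np.where(np.isnan(X), self.mean_, X)
        return (imputed - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


# ---------------------------------------------------------------------------
# Numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _objective(r, w, b, lam1, lam2):
    n = r.shape[0]
    loss = 0.0
    for i in range(n):
        if r[i] > 0.0:
            loss += r[i] * r[i]
    loss /= n
    pen = 0.0
    for j in range(w.shape[0]):
        pen += lam1 * abs(w[j]) + lam2 * w[j] * w[j]
    return loss + pen


@njit(cache=True)
def _cd_solve(X, y, lam1, lam2, tol, max_iter, w, b0):
    """Cyclic coordinate descent; returns (w, b, converged, obj, sweeps)."""
    n, m = X.shape
    b = b0
    # residual margin r_i = 1 - y_i (b + x_i' w)
    r = np.empty(n)
    for i in range(n):
        acc = b
        for j in range(m):
            if w[j] != 0.0:
                acc += X[i, j] * w[j]
        r[i] = 1.0 - y[i] * acc

    colsq = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        colsq[j] = 2.0 * s / n

    converged = False
    sweeps = 0
    use_active = False
    for sweep in range(max_iter):
        sweeps = sweep + 1
        max_delta = 0.0

        # intercept (unpenalized), curvature 2
        g = 0.0
        for i in range(n):
            if r[i] > 0.0:
                g -= 2.0 * r[i] * y[i]
        g /= n
        db = -g / 2.0
        if db != 0.0:
            b += db
            for i in range(n):
                r[i] -= y[i] * db
            if abs(db) > max_delta:
                max_delta = abs(db)

        for j in range(m):
            if use_active and w[j] == 0.0:
                continue
            h = colsq[j] + 2.0 * lam2
            if h <= 0.0:
                continue
            g = 2.0 * lam2 * w[j]
            for i in range(n):
                if r[i] > 0.0:
                    g -= 2.0 * r[i] * y[i] * X[i, j] / n
            u = w[j] - g / h
            thr = lam1 / h
            if u > thr:
                wj_new = u - thr
            elif u < -thr:
                wj_new = u + thr
            else:
                wj_new = 0.0
            d = wj_new - w[j]
            if d != 0.0:
                w[j] = wj_new
                for i in range(n):
                    r[i] -= y[i] * X[i, j] * d
                if abs(d) > max_delta:
                    max_delta = abs(d)

        if max_delta < tol:
            if use_active:
                # verify optimality over the full coordinate set
                use_active = False
                continue
            converged = True
            break
        use_active = True

    return w, b, converged, _objective(r, w, b, lam1, lam2), sweeps


@njit(cache=True)
def _intercept_only(y, tol, max_iter):
    """Optimal intercept of the squared-hinge loss with all weights zero."""
    n = y.shape[0]
    b = 0.0
    for _ in range(max_iter):
        g = 0.0
        for i in range(n):
            r = 1.0 - y[i] * b
            if r > 0.0:
                g -= 2.0 * r * y[i]
        g /= n
        db = -g / 2.0
        b += db
        if abs(db) < tol:
            break
    return b


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def _check_inputs(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite entries; impute/standardize first")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    if not set(np.unique(y)) <= {-1.0, 1.0}:
        raise ValueError("labels must be in {-1, +1}")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return X, y


def lambda1_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest L1 penalty for which the all-zero weight vector is optimal.

    Computed from the gradient of the loss at the intercept-only optimum
    b0: max_j |(2/n) sum_i y_i x_ij max(0, 1 - y_i b0)|.
    """
    X, y = _check_inputs(X, y)
    b0 = _intercept_only(y, 1e-12, 10_000)
    r = np.maximum(0.0, 1.0 - y * b0)
    grad = 2.0 * (X.T @ (y * r)) / X.shape[0]
    return float(np.abs(grad).max())


def fit(
    X: np.ndarray,
    y: np.ndarray,
    lambda1: float,
    lambda2: float,
    tol: float = 1e-6,
    max_iter: int = 1000,
    warm_start: SVMModel | None = None,
) -> SVMModel:
    """Fit one L1/L2 squared-hinge SVM at fixed penalties."""
    X, y = _check_inputs(X, y)
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("penalties must be nonnegative")
    if warm_start is not None:
        w = warm_start.coef.copy()
        b0 = warm_start.intercept
    else:
        w = np.zeros(X.shape[1])
        b0 = _intercept_only(y, 1e-12, 10_000)
    w, b, converged, obj, sweeps = _cd_solve(X, y, float(lambda1), float(lambda2), float(tol), int(max_iter), w, float(b0))
    w = np.where(np.abs(w) < _WEIGHT_EPS, 0.0, w)
    return SVMModel(
        intercept=float(b),
        coef=w,
        lambda1=float(lambda1),
        lambda2=float(lambda2),
        converged=bool(converged),
        objective=float(obj),
        n_sweeps=int(sweeps),
    )


def fit_path(
    X: np.ndarray,
    y: np.ndarray,
    lambda2: float,
    n_lambda1: int = 100,
    lambda1_min_ratio: float = 0.01,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> PathResult:
    """Warm-started solution path over a log-spaced decreasing lambda1 grid."""
    if n_lambda1 < 2:
        raise ValueError("n_lambda1 must be >= 2")
    X, y = _check_inputs(X, y)
    lmax = lambda1_max(X, y)
    if lmax <= 0:
        lmax = 1e-6
    grid = np.geomspace(lmax, lmax * lambda1_min_ratio, n_lambda1)
    models: list[SVMModel] = []
    prev: SVMModel | None = None
    for lam1 in grid:
        model = fit(X, y, lam1, lambda2, tol=tol, max_iter=max_iter, warm_start=prev)
        models.append(model)
        prev = model
    return PathResult(models=models, lambda1_grid=grid, lambda2=float(lambda2))


def decision_scores(model: SVMModel, X: np.ndarray) -> np.ndarray:
    """Linear decision score b + x'w per individual."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.coef.shape[0]:
        raise ValueError(f"X has {X.shape[1]} columns, model expects {model.coef.shape[0]}")
    return model.intercept + X @ model.coef


def objective(X: np.ndarray, y: np.ndarray, intercept: float, coef: np.ndarray, lambda1: float, lambda2: float) -> float:
    """The penalized squared-hinge objective at an arbitrary point."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    margin = 1.0 - y * (intercept + X @ coef)
    loss = np.square(np.maximum(0.0, margin)).mean()
    return float(loss + lambda1 * np.abs(coef).sum() + lambda2 * np.square(coef).sum())
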