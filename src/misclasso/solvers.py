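"""L1-penalized solvers for linear classifiers on {-1,+1} labels.

Two losses are supported for the penalized empirical risk

    (1/n) sum_i phi(y_i f_b(x_i)) + lam * sum_{j>=1} |b_j|,

with ``f_b(x) = b_0 + b.x`` and the intercept b_0 never penalized:

* quadratic, phi(t) = (1-t)^2 — on ±1 labels identical to penalized
  least squares of y on (1, X) because (1 - y f)^2 = (y - f)^2;
* logistic, phi(t) = log(1 + e^{-t}).

Both are solved by cyclic coordinate descent (the logistic loss through a
proximal-Newton outer loop); every converged fit carries a verifiable KKT
certificate.  Gradient conventions: for the quadratic loss the stationarity
conditions use (2/n) X'r (the factor 2 from differentiating the square);
for the logistic loss (1/n) X'(p - y01) with y01 = (y+1)/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _cd
from .data import Dataset

__all__ = [
    "FitResult",
    "CVResult",
    "soft_threshold",
    "fit_lasso",
    "fit_lasso_quadratic",
    "fit_lasso_logistic",
    "lambda_max",
    "lambda_grid",
    "fit_path",
    "cross_validate",
    "fit_cv",
    "predict_labels",
    "penalized_objective",
    "kkt_residuals",
]

LOSSES = ("quadratic", "logistic")
DEFAULT_TOL = 1e-7
DEFAULT_MAX_ITER = 100_000


@dataclass(frozen=True)
class FitResult:
    """A fitted penalized linear classifier.

    ``coef`` has length p+1 with the (unpenalized) intercept at index 0.
    ``objective`` is the penalized empirical risk at ``coef``, recomputable
    from the data to within 1e-8.
    """

    coef: np.ndarray
    loss: str
    lam: float
    n_iter: int
    converged: bool
    objective: float

    @property
    def intercept(self) -> float:
        return float(self.coef[0])

    @property
    def slopes(self) -> np.ndarray:
        return self.coef[1:]

    @property
    def support(self) -> np.ndarray:
        """1-based indices of nonzero slopes."""
        return np.flatnonzero(self.slopes) + 1


@dataclass(frozen=True)
class CVResult:
    """K-fold cross-validation curve over a decreasing lambda grid."""

    lam_grid: np.ndarray
    cv_loss: np.ndarray
    cv_se: np.ndarray
    lam_selected: float
    loss: str
    fold_assignment_seed: int


def soft_threshold(z: float, t: float) -> float:
    """sign(z) * max(|z| - t, 0) — the scalar Lasso shrinkage map."""
    if t < 0:
        raise ValueError("threshold must be >= 0")
    return float(np.sign(z) * max(abs(z) - t, 0.0))


def _check_data(data: Dataset, lam: float):
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if not (np.all(np.isfinite(data.X)) and np.all(np.isfinite(data.y))):
        raise ValueError("non-finite entries in data")


def _as_fortran(X: np.ndarray) -> np.ndarray:
    return np.asfortranarray(X, dtype=np.float64)


def penalized_objective(coef: np.ndarray, data: Dataset, loss: str, lam: float) -> float:
    """Penalized empirical risk Q̄(f_coef) + lam * |slopes|_1."""
    coef = np.asarray(coef, dtype=float)
    f = coef[0] + data.X @ coef[1:]
    t = data.y * f
    if loss == "quadratic":
        risk = np.mean((1.0 - t) ** 2)
    elif loss == "logistic":
        risk = np.mean(np.logaddexp(0.0, -t))
    else:
        raise ValueError(f"unknown loss {loss!r}")
    return float(risk + lam * np.abs(coef[1:]).sum())


def _gradient(coef: np.ndarray, data: Dataset, loss: str) -> np.ndarray:
    """Gradient of the (unpenalized) empirical risk; length p+1."""
    n = data.n
    f = coef[0] + data.X @ coef[1:]
    if loss == "quadratic":
        r = data.y - f
        g0 = -2.0 * r.mean()
        g = -(2.0 / n) * (data.X.T @ r)
    else:
        from scipy.special import expit

        resid = expit(f) - (data.y + 1.0) / 2.0  # p_i - y01_i
        g0 = resid.mean()
        g = data.X.T @ resid / n
    return np.concatenate(([g0], g))


def kkt_residuals(fit: FitResult, data: Dataset) -> dict:
    """Subgradient-optimality residuals of a fit.

    Returns the largest violations of: the intercept stationarity, the
    inequality |grad_j| <= lam on zero slopes, and the equality
    grad_j = -lam*sign(b_j) on nonzero slopes.
    """
    g = _gradient(fit.coef, data, fit.loss)
    b = fit.slopes
    zero = b == 0.0
    viol_zero = float(np.max(np.abs(g[1:][zero]) - fit.lam, initial=-np.inf))
    viol_nonzero = float(
        np.max(np.abs(g[1:][~zero] + fit.lam * np.sign(b[~zero])), initial=0.0)
    )
    return {
        "intercept": abs(float(g[0])),
        "zero": max(viol_zero, 0.0),
        "nonzero": viol_nonzero,
    }


def check_kkt(fit: FitResult, data: Dataset, tol: float = DEFAULT_TOL) -> bool:
    """True iff the KKT certificate holds with slack 10*tol."""
    r = kkt_residuals(fit, data)
    slack = 10.0 * tol
    return r["intercept"] <= slack and r["zero"] <= slack and r["nonzero"] <= slack


def _run_solver(X_f, y, loss, lam, tol, max_iter, b, b0, lam_prev=None):
    # lam_prev drives the sequential strong-rule screen; None disables it
    if lam_prev is None:
        lam_prev = 1e300
    if loss == "quadratic":
        w = np.full(y.shape[0], 2.0)
        b0, it, conv = _cd.weighted_lasso(X_f, y, w, lam, lam_prev, tol, max_iter, b, b0)
    else:
        y01 = (y + 1.0) / 2.0
        b0, it, conv = _cd.logistic_lasso(X_f, y01, lam, lam_prev, tol, max_iter, 200, b, b0)
    return b0, it, conv


def fit_lasso(
    data: Dataset,
    loss: str,
    lam: float,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    warm_start: Optional[np.ndarray] = None,
) -> FitResult:
    """Fit the l1-penalized classifier for either loss.

    ``warm_start`` is a full coefficient vector (intercept first) used to
    initialize the coordinate descent.  Non-convergence returns a result
    with ``converged=False`` and a warning, never an exception.
    """
    if loss not in LOSSES:
        raise ValueError(f"loss must be one of {LOSSES}")
    _check_data(data, lam)
    if data.n < 2:
        raise ValueError("need n >= 2 observations")
    X_f = _as_fortran(data.X)
    if warm_start is not None:
        ws = np.asarray(warm_start, dtype=float)
        b0, b = float(ws[0]), ws[1:].copy()
    else:
        b0, b = 0.0, np.zeros(data.p)
    b0, it, conv = _run_solver(X_f, data.y, loss, lam, tol, max_iter, b, b0)
    if not conv:
        warnings.warn(f"{loss} lasso did not converge at lam={lam:g}")
    coef = np.concatenate(([b0], b))
    return FitResult(
        coef=coef,
        loss=loss,
        lam=float(lam),
        n_iter=int(it),
        converged=bool(conv),
        objective=penalized_objective(coef, data, loss, lam),
    )


def fit_lasso_quadratic(data: Dataset, lam: float, **kw) -> FitResult:
    """Quadratic-loss Lasso: coordinate descent on (1/n)||y - f||^2 + lam|b|_1."""
    return fit_lasso(data, "quadratic", lam, **kw)


def fit_lasso_logistic(data: Dataset, lam: float, **kw) -> FitResult:
    """Logistic-loss Lasso via proximal Newton with coordinate-descent inner."""
    return fit_lasso(data, "logistic", lam, **kw)


def lambda_max(data: Dataset, loss: str) -> float:
    """Smallest lambda at which all penalized coordinates are zero.

    At the intercept-only optimum the stationarity condition on slope j is
    |grad_j| <= lam; lambda_max is the largest such gradient entry.
    """
    n = data.n
    if loss == "quadratic":
        r = data.y - data.y.mean()
        return float(np.max(np.abs(2.0 / n * (data.X.T @ r))))
    elif loss == "logistic":
        pbar = float(np.mean(data.y == 1.0))
        resid = pbar - (data.y + 1.0) / 2.0
        return float(np.max(np.abs(data.X.T @ resid / n)))
    raise ValueError(f"unknown loss {loss!r}")


def _null_intercept(y: np.ndarray, loss: str) -> float:
    if loss == "quadratic":
        return float(y.mean())
    npos = float(np.sum(y == 1.0))
    nneg = float(np.sum(y == -1.0))
    if npos == 0.0 or nneg == 0.0:
        # single-class fold: the logistic MLE diverges; cap the intercept
        return np.sign(npos - nneg) * 30.0
    return float(np.log(npos / nneg))


def lambda_grid(data: Dataset, loss: str, grid_size: int = 100,
                lam_min_ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced decreasing grid from lambda_max down to
    lam_min_ratio * lambda_max."""
    lmax = lambda_max(data, loss)
    if lmax <= 0:
        return np.zeros(grid_size)
    return np.geomspace(lmax, lam_min_ratio * lmax, grid_size)


def fit_path(
    data: Dataset,
    loss: str,
    lambdas: Sequence[float],
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> np.ndarray:
    """Warm-started coefficient path over a decreasing lambda sequence.

    Returns an array of shape (len(lambdas), p+1).
    """
    _check_data(data, 0.0)
    X_f = _as_fortran(data.X)
    lambdas = np.asarray(lambdas, dtype=float)
    coefs = np.empty((lambdas.size, data.p + 1))
    b = np.zeros(data.p)
    b0 = _null_intercept(data.y, loss)
    lam_prev = None
    for i, lam in enumerate(lambdas):
        b0, _, conv = _run_solver(X_f, data.y, loss, lam, tol, max_iter, b, b0,
                                  lam_prev=lam_prev)
        lam_prev = lam
        if not conv:
            warnings.warn(f"path fit did not converge at lam={lam:g}")
        coefs[i, 0] = b0
        coefs[i, 1:] = b
    return coefs


def _heldout_loss(coef: np.ndarray, X: np.ndarray, y: np.ndarray, loss: str) -> float:
    f = coef[0] + X @ coef[1:]
    t = y * f
    if loss == "quadratic":
        return float(np.mean((1.0 - t) ** 2))
    return float(np.mean(np.logaddexp(0.0, -t)))


def cross_validate(
    data: Dataset,
    loss: str,
    n_folds: int = 10,
    grid_size: int = 100,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    patience: Optional[int] = None,
) -> CVResult:
    """K-fold CV over a shared log-spaced lambda grid.

    The held-out criterion is the loss phi itself (squared error for the
    quadratic loss, log-loss for the logistic).  The selected lambda
    minimizes the mean CV curve (the "lambda.min" rule); ties go to the
    larger lambda.  Folds are a seeded random partition into contiguous
    blocks of a permutation, so the result is reproducible from ``seed``.

    All folds walk the path in lockstep (warm-started from the previous
    grid point).  With ``patience`` set, the descent stops once the mean
    CV curve has not improved for that many consecutive grid points; the
    returned grid is truncated accordingly.  This skips the saturated
    small-lambda tail of the path, which is never selected once the curve
    has turned upward for good.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if data.n < n_folds:
        raise ValueError("need n >= n_folds")
    grid = lambda_grid(data, loss, grid_size)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(data.n)
    folds = np.array_split(perm, n_folds)

    state = []  # (X_f, ytr, Xte, yte, b, b0, intercept_only)
    for k, test_idx in enumerate(folds):
        mask = np.ones(data.n, dtype=bool)
        mask[test_idx] = False
        ytr = data.y[mask]
        intercept_only = np.unique(ytr).size < 2
        if intercept_only:
            warnings.warn(f"fold {k} has a single class; using intercept-only fits")
        X_f = _as_fortran(data.X[mask])
        state.append([X_f, ytr, data.X[test_idx], data.y[test_idx],
                      np.zeros(data.p), _null_intercept(ytr, loss), intercept_only])

    losses = np.empty((n_folds, grid.size))
    n_used = grid.size
    best_i = 0
    running = np.empty(grid.size)
    for i, lam in enumerate(grid):
        lam_prev = grid[i - 1] if i > 0 else None
        for k, st in enumerate(state):
            X_f, ytr, Xte, yte, b, b0, intercept_only = st
            if not intercept_only:
                b0, _, conv = _run_solver(X_f, ytr, loss, lam, tol, max_iter, b, b0,
                                          lam_prev=lam_prev)
                if not conv:
                    warnings.warn(f"CV path fit did not converge at lam={lam:g}")
                st[5] = b0
            losses[k, i] = _heldout_loss(np.concatenate(([b0], b)), Xte, yte, loss)
        running[i] = losses[:, i].mean()
        if running[i] < running[best_i] - 1e-12:
            best_i = i
        if patience is not None and i - best_i >= patience:
            n_used = i + 1
            break
    grid = grid[:n_used]
    losses = losses[:, :n_used]
    cv_loss = losses.mean(axis=0)
    cv_se = losses.std(axis=0, ddof=1) / np.sqrt(n_folds)
    lam_selected = float(grid[int(np.argmin(cv_loss))])
    return CVResult(
        lam_grid=grid,
        cv_loss=cv_loss,
        cv_se=cv_se,
        lam_selected=lam_selected,
        loss=loss,
        fold_assignment_seed=int(seed),
    )


def fit_cv(
    data: Dataset,
    loss: str,
    n_folds: int = 10,
    grid_size: int = 100,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    patience: Optional[int] = None,
) -> tuple[FitResult, CVResult]:
    """Cross-validate, then refit on all data at the selected lambda
    (warm-started down the path from lambda_max)."""
    cv = cross_validate(data, loss, n_folds, grid_size, seed, tol, max_iter, patience)
    sub = cv.lam_grid[cv.lam_grid >= cv.lam_selected]
    coefs = fit_path(data, loss, sub, tol=tol, max_iter=max_iter)
    coef = coefs[-1]
    fit = FitResult(
        coef=coef,
        loss=loss,
        lam=cv.lam_selected,
        n_iter=0,
        converged=True,
        objective=penalized_objective(coef, data, loss, cv.lam_selected),
    )
    return fit, cv


def predict_labels(coef: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Classify by the sign of the linear index; ties (f = 0) go to +1."""
    coef = np.asarray(coef, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != coef.size - 1:
        raise ValueError("dimension mismatch between coef and X")
    f = coef[0] + X @ coef[1:]
    return np.where(f >= 0.0, 1.0, -1.0)
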