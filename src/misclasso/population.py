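"""Population-level quantities of the misspecified classification theory.

For a known generative model (single-index, equicorrelated Gaussian
design) this module computes the targets the penalized estimators converge
to and the components of their excess-risk decomposition:

* ``b*`` — the population minimizer of the expected convex risk
  ``Q(f_b) = E phi(Y f_b(X))`` over linear classifiers, for the quadratic
  loss (closed-form normal equations with a Monte-Carlo moment) and the
  logistic loss (large-sample unpenalized fit);
* ``gamma`` — the proportionality constant between the quadratic
  population slopes and the true index direction under the elliptical
  design;
* the Kullback-Leibler distance between Bernoulli laws and the
  approximation-error functionals it enters;
* the margin probability ``P(|b*.x~| <= c |x~|_inf)`` appearing in the
  estimation-risk bound.

All Monte-Carlo estimates are seeded and report a standard-error scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

from .data import ModelSpec, Dataset, design_covariance, index_variance, sample_design, sample_labels
from .solvers import fit_lasso

__all__ = [
    "PopulationTarget",
    "population_quadratic_minimizer",
    "population_logistic_minimizer",
    "gamma_coefficient",
    "kl_divergence",
    "approximation_error_quadratic",
    "approximation_error_logistic",
    "margin_probability",
]

_CHUNK = 100_000


@dataclass(frozen=True)
class PopulationTarget:
    """A population risk minimizer b* with its provenance.

    ``se`` is a scalar Monte-Carlo error scale (a bound on the per-entry
    standard error), not a full covariance.
    """

    coef_star: np.ndarray
    loss: str
    method: str
    mc_size: int
    se: float

    @property
    def intercept(self) -> float:
        return float(self.coef_star[0])

    @property
    def slopes(self) -> np.ndarray:
        return self.coef_star[1:]


def _augmented_covariance(spec: ModelSpec) -> np.ndarray:
    """H~ = E[x~ x~'] with x~ = (1, x): block-diagonal [[1, 0], [0, H]]
    because the design is centered."""
    H = design_covariance(spec.p, spec.rho)
    Ht = np.zeros((spec.p + 1, spec.p + 1))
    Ht[0, 0] = 1.0
    Ht[1:, 1:] = H
    return Ht


def population_quadratic_minimizer(
    spec: ModelSpec, m: int = 10**6, seed: int = 0
) -> PopulationTarget:
    """b*quad = H~^{-1} E[x~ (2 eta(x) - 1)].

    The augmented second-moment matrix H~ is assembled in closed form from
    rho; the cross-moment vector is estimated by Monte Carlo with m design
    draws (in chunks).  For the quadratic loss the normal equations are
    exact, so the only error is the Monte-Carlo error of the moment.
    """
    if m < 10**4:
        raise ValueError("m must be >= 10^4")
    rng = np.random.default_rng(seed)
    psum = np.zeros(spec.p + 1)
    psumsq = np.zeros(spec.p + 1)
    done = 0
    while done < m:
        sz = min(_CHUNK, m - done)
        X = sample_design(sz, spec, seed=int(rng.integers(2**31)))
        u = spec.intercept + X @ spec.slopes
        t = 2.0 * np.asarray(spec.link(u), dtype=float) - 1.0
        v = np.column_stack([t, X * t[:, None]])
        psum += v.sum(axis=0)
        psumsq += (v * v).sum(axis=0)
        done += sz
    moment = psum / m
    mom_var = psumsq / m - moment**2
    mom_se = np.sqrt(np.maximum(mom_var, 0.0) / m)
    Ht = _augmented_covariance(spec)
    coef = np.linalg.solve(Ht, moment)
    # propagate the moment SE through the linear solve (inf-norm bound)
    se = float(np.linalg.norm(np.linalg.inv(Ht), np.inf) * mom_se.max())
    return PopulationTarget(coef_star=coef, loss="quadratic",
                            method="monte_carlo", mc_size=m, se=se)


def quadratic_minimizer_index_reduced(
    spec: ModelSpec, m: int = 10**6, seed: int = 0
) -> np.ndarray:
    """Cross-check route for b*quad through the 1-D index integral.

    Under the elliptical design, E[x (2 eta - 1)] = gamma * H beta_ring, so
    b*quad = (2 E[g(beta.x~)] - 1, gamma * beta_ring).  Both expectations
    are over the scalar index, which is exactly Gaussian.
    """
    rng = np.random.default_rng(seed)
    sd = np.sqrt(index_variance(spec))
    u = spec.intercept + sd * rng.standard_normal(m)
    g = np.asarray(spec.link(u), dtype=float)
    b0 = 2.0 * g.mean() - 1.0
    gam = gamma_coefficient(spec, m=m, seed=int(rng.integers(2**31)))
    return np.concatenate(([b0], gam * spec.slopes))


def population_logistic_minimizer(
    spec: ModelSpec, m: int = 10**6, seed: int = 0
) -> PopulationTarget:
    """b*log estimated as the unpenalized logistic fit on an m-draw sample.

    There is no closed form for the logistic projection, so the population
    minimizer is approximated by its empirical version at a large Monte
    Carlo sample size; the standard-error scale comes from a half-sample
    split (half the difference between the two half-sample fits).
    """
    if m < 10**4:
        raise ValueError("m must be >= 10^4")
    rng = np.random.default_rng(seed)
    X = sample_design(m, spec, seed=int(rng.integers(2**31)))
    y = sample_labels(X, spec, seed=int(rng.integers(2**31)))
    data = Dataset(X=X, y=y)
    fit = fit_lasso(data, "logistic", lam=0.0, tol=1e-8)
    h = m // 2
    fits = [
        fit_lasso(Dataset(X=X[:h], y=y[:h]), "logistic", lam=0.0, tol=1e-8),
        fit_lasso(Dataset(X=X[h:], y=y[h:]), "logistic", lam=0.0, tol=1e-8),
    ]
    se = float(np.max(np.abs(fits[0].coef - fits[1].coef)) / 2.0)
    return PopulationTarget(coef_star=fit.coef, loss="logistic",
                            method="monte_carlo", mc_size=m, se=se)


def gamma_coefficient(spec: ModelSpec, m: int = 10**6, seed: int = 0) -> float:
    """The proportionality constant gamma = 2 E[g(beta.x~) beta_ring.x] / (beta_ring' H beta_ring).

    The denominator is closed-form from rho; the numerator is a Monte-Carlo
    average over the scalar index beta_ring.x, whose law is exactly
    N(0, beta_ring' H beta_ring).  gamma is nonzero whenever g is strictly
    monotone, and then the quadratic population slopes are gamma * beta_ring.
    """
    v = index_variance(spec)
    if v == 0.0:
        raise ValueError("gamma is undefined when all slopes are zero")
    rng = np.random.default_rng(seed)
    z = np.sqrt(v) * rng.standard_normal(m)
    g = np.asarray(spec.link(spec.intercept + z), dtype=float)
    return float(2.0 * np.mean(g * z) / v)


def kl_divergence(pi1: float, pi2: float) -> float:
    """Kullback-Leibler distance between Bernoulli(pi1) and Bernoulli(pi2).

    Uses the 0*log 0 = 0 convention for pi1 in {0, 1}; returns +inf when
    pi2 is degenerate but pi1 puts mass where pi2 does not.
    """
    if not (0.0 <= pi1 <= 1.0 and 0.0 <= pi2 <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    terms = 0.0
    for a, b in ((pi1, pi2), (1.0 - pi1, 1.0 - pi2)):
        if a == 0.0:
            continue
        if b == 0.0:
            return float("inf")
        terms += a * np.log(a / b)
    return float(max(terms, 0.0))


def _kl_vec(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Vectorized Bernoulli KL with the 0 log 0 convention."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(p1 > 0.0, p1 * np.log(p1 / p2), 0.0)
        t2 = np.where(p1 < 1.0, (1.0 - p1) * np.log((1.0 - p1) / (1.0 - p2)), 0.0)
    return np.maximum(t1 + t2, 0.0)


def _mc_mean(spec: ModelSpec, func, m: int, seed: int):
    """Chunked Monte-Carlo mean and SE of func(X) over the design law."""
    rng = np.random.default_rng(seed)
    s = 0.0
    ssq = 0.0
    done = 0
    while done < m:
        sz = min(_CHUNK, m - done)
        X = sample_design(sz, spec, seed=int(rng.integers(2**31)))
        v = np.asarray(func(X), dtype=float)
        s += v.sum()
        ssq += (v * v).sum()
        done += sz
    mean = s / m
    var = max(ssq / m - mean * mean, 0.0)
    return float(mean), float(np.sqrt(var / m))


def approximation_error_quadratic(
    spec: ModelSpec, target: PopulationTarget, m: int = 10**6, seed: int = 0
):
    """E[(2 eta(x) - 1 - b*quad . x~)^2] — how far the conditional mean of Y
    is from the best linear function.  Returns (estimate, se)."""
    if target.loss != "quadratic":
        raise ValueError("target must be a quadratic-loss minimizer")
    b = target.coef_star

    def sq_err(X):
        u = spec.intercept + X @ spec.slopes
        t = 2.0 * np.asarray(spec.link(u), dtype=float) - 1.0
        return (t - (b[0] + X @ b[1:])) ** 2

    return _mc_mean(spec, sq_err, m, seed)


@dataclass(frozen=True)
class LogisticApproxError:
    """KL approximation error with its Monte-Carlo SE and, when a margin
    delta is supplied, the squared-error upper bound (2 delta (1-delta))^{-1}
    E[(eta - eta_log)^2]."""

    kl: float
    se: float
    bound: Optional[float] = None


def approximation_error_logistic(
    spec: ModelSpec,
    target: PopulationTarget,
    m: int = 10**6,
    seed: int = 0,
    delta: Optional[float] = None,
) -> LogisticApproxError:
    """E[KL(eta(x), eta_log(b*log . x~))] with eta_log(u) = 1/(1+e^{-u}).

    Vanishes when the true link is logistic (the model is well specified).
    With ``delta`` in (0, 1), also evaluates the upper bound
    (2 delta (1 - delta))^{-1} E[(eta - eta_log)^2].
    """
    if target.loss != "logistic":
        raise ValueError("target must be a logistic-loss minimizer")
    if delta is not None and not (0.0 < delta < 1.0):
        raise ValueError("delta must be in (0, 1)")
    b = target.coef_star

    def kl_terms(X):
        eta = np.asarray(spec.link(spec.intercept + X @ spec.slopes), dtype=float)
        eta_log = expit(b[0] + X @ b[1:])
        return _kl_vec(eta, eta_log)

    kl, se = _mc_mean(spec, kl_terms, m, seed)
    bound = None
    if delta is not None:

        def sq(X):
            eta = np.asarray(spec.link(spec.intercept + X @ spec.slopes), dtype=float)
            eta_log = expit(b[0] + X @ b[1:])
            return (eta - eta_log) ** 2

        msq, _ = _mc_mean(spec, sq, m, seed)
        bound = msq / (2.0 * delta * (1.0 - delta))
    return LogisticApproxError(kl=kl, se=se, bound=bound)


def margin_probability(
    target: PopulationTarget, c: float, spec: ModelSpec, m: int = 10**6, seed: int = 0
):
    """P(|b* . x~| <= c |x~|_inf), the small-margin term of the
    estimation-risk bound; x~ = (1, x) so |x~|_inf >= 1.  Returns
    (estimate, se)."""
    if c < 0:
        raise ValueError("c must be >= 0")
    b = target.coef_star

    def indicator(X):
        f = b[0] + X @ b[1:]
        xinf = np.maximum(1.0, np.abs(X).max(axis=1))
        return (np.abs(f) <= c * xinf).astype(float)

    return _mc_mean(spec, indicator, m, seed)
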