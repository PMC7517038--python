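"""Design-quality functionals over the estimation cone.

For a support set T (1-based predictor indices), T~ = T u {0} (the
intercept), and xi > 1, the cone is

    C(xi) = { b in R^{p+1} : |b_{T^c}|_1 <= xi |b_{T~}|_1 }.

Over this cone we compute, for a second-moment matrix G (either the
empirical X~'X~/n or the population H~):

* restricted eigenvalue        RE(xi)  = inf b'Gb / |b|_2^2
* compatibility factor         K(xi)   = inf |T| b'Gb / |b_T|_1^2
* cone invertibility factor    F_q(xi) = inf |T|^{1/q} |Gb|_inf / |b|_q

These are nonconvex ratio minimizations; except in tiny dimension they are
computed by seeded multi-start local search and the returned value is a
certified UPPER bound on the true infimum: the certificate vector lies in
the cone and reproduces the value exactly.  For p+1 <= 3 an exhaustive
sphere-grid oracle is available (``method="exact_grid"``).

Note the normalizations differ: the cone constraint always uses T~ (with
the intercept) while the compatibility factor's |b_T|_1 excludes it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .data import ModelSpec
from .population import _augmented_covariance

__all__ = [
    "ConeSpec",
    "ConeFactorResult",
    "in_cone",
    "cone_factor",
    "cif_empirical",
    "cif_population",
    "restricted_eigenvalue",
    "compatibility_factor",
]


@dataclass(frozen=True)
class ConeSpec:
    """The cone C(xi) for a given support T and norm index q.

    ``support_T`` holds 1-based predictor indices; ``q`` may be any value
    in [1, inf] (math.inf for the sup-norm), and only enters the CIF
    through the factor |T|^{1/q}.
    """

    xi: float
    support_T: tuple = field(default=())
    q: float = math.inf

    def __post_init__(self):
        if not self.xi > 1.0:
            raise ValueError("xi must be > 1")
        if not (1.0 <= self.q):
            raise ValueError("q must be >= 1")
        T = tuple(sorted(int(j) for j in self.support_T))
        if any(j < 1 for j in T):
            raise ValueError("support indices are 1-based predictor indices")
        object.__setattr__(self, "support_T", T)

    def masks(self, p: int):
        """Boolean masks (t_tilde, t_comp) over coordinates 0..p."""
        t_tilde = np.zeros(p + 1, dtype=bool)
        t_tilde[0] = True
        t_tilde[list(self.support_T)] = True
        t_comp = ~t_tilde
        return t_tilde, t_comp


@dataclass(frozen=True)
class ConeFactorResult:
    """Best-found value of a cone functional with its certificate."""

    value: float
    argmin: np.ndarray
    n_restarts: int
    method: str


def in_cone(b: np.ndarray, cone: ConeSpec) -> bool:
    """True iff |b_{T^c}|_1 <= xi |b_{T~}|_1 (closed cone: equality counts)."""
    b = np.asarray(b, dtype=float)
    t_tilde, t_comp = cone.masks(b.size - 1)
    return float(np.abs(b[t_comp]).sum()) <= cone.xi * float(np.abs(b[t_tilde]).sum()) + 1e-12


def _objective_rows(kind: str, G: np.ndarray, cone: ConeSpec, B: np.ndarray) -> np.ndarray:
    """Evaluate the functional on each row of B (no cone check)."""
    p = G.shape[0] - 1
    T = list(cone.support_T)
    sT = max(len(T), 1)
    if kind == "cif":
        gb = B @ G
        num = np.abs(gb).max(axis=1)
        if math.isinf(cone.q):
            denom = np.abs(B).max(axis=1)
            fac = 1.0
        else:
            denom = (np.abs(B) ** cone.q).sum(axis=1) ** (1.0 / cone.q)
            fac = sT ** (1.0 / cone.q)
        return fac * num / denom
    quad = np.einsum("ij,jk,ik->i", B, G, B)
    if kind == "re":
        return quad / (B * B).sum(axis=1)
    if kind == "compat":
        l1T = np.abs(B[:, T]).sum(axis=1)
        with np.errstate(divide="ignore"):
            return np.where(l1T > 0.0, sT * quad / l1T**2, np.inf)
    raise ValueError(f"unknown functional {kind!r}")


def _objective(kind, G, cone, b) -> float:
    return float(_objective_rows(kind, G, cone, b.reshape(1, -1))[0])


def _project_to_cone(b: np.ndarray, cone: ConeSpec) -> Optional[np.ndarray]:
    """Scale the off-support block down onto the cone boundary if needed."""
    b = np.asarray(b, dtype=float).copy()
    t_tilde, t_comp = cone.masks(b.size - 1)
    lhs = np.abs(b[t_comp]).sum()
    rhs = cone.xi * np.abs(b[t_tilde]).sum()
    if lhs <= rhs:
        return b if np.any(b != 0.0) else None
    if rhs == 0.0:
        return None
    b[t_comp] *= rhs / lhs
    return b


def _random_cone_points(cone: ConeSpec, p: int, n: int, rng) -> np.ndarray:
    """Sample points in the cone: Gaussian on T~, off-support block rescaled
    to a uniform fraction of the allowed l1 budget."""
    t_tilde, t_comp = cone.masks(p)
    B = np.zeros((n, p + 1))
    B[:, t_tilde] = rng.standard_normal((n, t_tilde.sum()))
    if t_comp.sum() > 0:
        U = rng.standard_normal((n, t_comp.sum()))
        budget = cone.xi * np.abs(B[:, t_tilde]).sum(axis=1) * rng.random(n)
        norm = np.abs(U).sum(axis=1)
        norm[norm == 0.0] = 1.0
        B[:, t_comp] = U * (budget / norm)[:, None]
    return B


def _sphere_grid(dim: int, n_points: int, rng) -> np.ndarray:
    if dim == 1:
        return np.array([[1.0], [-1.0]])
    if dim == 2:
        th = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
        return np.column_stack([np.cos(th), np.sin(th)])
    if dim == 3:
        # Fibonacci sphere: near-uniform covering of S^2
        i = np.arange(n_points)
        phi = np.pi * (3.0 - np.sqrt(5.0)) * i
        z = 1.0 - 2.0 * (i + 0.5) / n_points
        r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
        return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    raise ValueError("exact_grid supports p+1 <= 3 only")


def cone_factor(
    G: np.ndarray,
    cone: ConeSpec,
    kind: str,
    restarts: int = 256,
    seed: int = 0,
    extra_starts: Optional[Iterable[np.ndarray]] = None,
    method: str = "random_restart",
    grid_points: int = 400_000,
) -> ConeFactorResult:
    """Minimize a cone functional over C(xi) \\ {0}.

    ``extra_starts`` seeds the search with known-good candidates (e.g. the
    certificate found for a smaller xi, whose cone is nested inside this
    one), which makes monotonicity in xi hold by construction.
    """
    G = np.asarray(G, dtype=float)
    p = G.shape[0] - 1
    if not np.any(G):
        raise ValueError("degenerate all-zero second-moment matrix")
    rng = np.random.default_rng(seed)

    candidates = []
    if method == "exact_grid":
        B = _sphere_grid(p + 1, grid_points, rng)
        keep = [i for i in range(B.shape[0]) if in_cone(B[i], cone)]
        B = B[keep]
        vals = _objective_rows(kind, G, cone, B)
        vals = np.where(np.isfinite(vals), vals, np.inf)
        i = int(np.argmin(vals))
        return ConeFactorResult(value=float(vals[i]), argmin=B[i],
                                n_restarts=B.shape[0], method="exact_grid")

    # deterministic starts: smallest eigenvectors of G, projected onto the cone
    evals, evecs = np.linalg.eigh(G)
    for k in range(min(3, p + 1)):
        v = _project_to_cone(evecs[:, k], cone)
        if v is not None:
            candidates.append(v)
    if extra_starts is not None:
        for v in extra_starts:
            v = _project_to_cone(np.asarray(v, dtype=float), cone)
            if v is not None:
                candidates.append(v)
    B = _random_cone_points(cone, p, restarts, rng)
    candidates.extend(B[i] for i in range(B.shape[0]) if np.any(B[i] != 0.0))

    cand = np.array(candidates)
    vals = _objective_rows(kind, G, cone, cand)
    vals = np.where(np.isfinite(vals), vals, np.inf)
    order = np.argsort(vals)
    best_b, best_v = cand[order[0]], float(vals[order[0]])

    # local polish of the few best starts (penalized, scale-free objective)
    t_tilde, t_comp = cone.masks(p)

    def penalized(b):
        nrm = np.abs(b).sum()
        if nrm == 0.0:
            return np.inf
        b = b / nrm
        viol = np.abs(b[t_comp]).sum() - cone.xi * np.abs(b[t_tilde]).sum()
        pen = 1e3 * max(viol, 0.0)
        proj = _project_to_cone(b, cone)
        if proj is None:
            return np.inf
        return _objective(kind, G, cone, proj) + pen

    n_polish = min(8, len(order))
    maxiter = 400 * (p + 1)
    for idx in order[:n_polish]:
        res = minimize(penalized, cand[idx] / np.abs(cand[idx]).sum(),
                       method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-9, "fatol": 1e-12})
        proj = _project_to_cone(res.x, cone)
        if proj is None:
            continue
        v = _objective(kind, G, cone, proj)
        if v < best_v:
            best_v, best_b = v, proj
    best_b = best_b / np.abs(best_b).sum()
    best_v = _objective(kind, G, cone, best_b)
    return ConeFactorResult(value=float(best_v), argmin=best_b,
                            n_restarts=restarts, method="random_restart")


def _empirical_gram(X_design: np.ndarray) -> np.ndarray:
    X = np.asarray(X_design, dtype=float)
    n = X.shape[0]
    Xt = np.column_stack([np.ones(n), X])
    return Xt.T @ Xt / n


def cif_empirical(X_design: np.ndarray, cone: ConeSpec, restarts: int = 256,
                  seed: int = 0, **kw) -> ConeFactorResult:
    """Empirical cone invertibility factor F_bar_q(xi) of a design matrix."""
    return cone_factor(_empirical_gram(X_design), cone, "cif", restarts, seed, **kw)


def cif_population(spec: ModelSpec, cone: ConeSpec, restarts: int = 256,
                   seed: int = 0, **kw) -> ConeFactorResult:
    """Population CIF F_q(xi), with H~ assembled in closed form from rho."""
    return cone_factor(_augmented_covariance(spec), cone, "cif", restarts, seed, **kw)


def restricted_eigenvalue(X_design: np.ndarray, cone: ConeSpec, restarts: int = 256,
                          seed: int = 0, **kw) -> ConeFactorResult:
    """Restricted eigenvalue RE(xi) of a design matrix."""
    return cone_factor(_empirical_gram(X_design), cone, "re", restarts, seed, **kw)


def compatibility_factor(X_design: np.ndarray, cone: ConeSpec, restarts: int = 256,
                         seed: int = 0, **kw) -> ConeFactorResult:
    """Compatibility factor K(xi) of a design matrix."""
    return cone_factor(_empirical_gram(X_design), cone, "compat", restarts, seed, **kw)
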