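"""Numba kernels: cyclic coordinate descent for weighted l1-penalized
least squares, and the proximal-Newton (IRLS) outer loop for the logistic
loss.

Conventions (fixed throughout the package):

* the empirical risk carries a 1/n factor, and the quadratic loss is
  ``(1/n) sum (y_i - f_i)^2`` — the weighted kernel below minimizes
  ``(1/(2n)) sum w_i (z_i - f_i)^2 + lam |b|_1``, so the quadratic problem
  is the special case ``w = 2, z = y``;
* the intercept (held separately from the slope vector) is never
  penalized;
* convergence is declared when the largest coordinate change in a full
  sweep falls below ``tol``.

Sweeps are restricted to a screened working set chosen by the sequential
strong rule (include j when the gradient at the previous path point
exceeds 2*lam - lam_prev); after convergence on the working set the KKT
conditions are verified on ALL coordinates and any violators are added,
so the screened solution is exact, not approximate.  Passing
``lam_prev = lam_max`` (or anything >= 2*lam) disables screening.

Design matrices are expected in Fortran order so column slices are
contiguous.
"""

import numpy as np
from numba import njit

WEIGHT_FLOOR = 1e-5  # IRLS weight clip


@njit(cache=True)
def _soft(z, t):
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


@njit(cache=True)
def _sweep(X, w, r, b, lam, den, screen, active_only):
    """One cyclic sweep over screened slope coordinates; updates b and the
    residual r in place, returns the largest absolute coefficient change."""
    n, p = X.shape
    maxd = 0.0
    for j in range(p):
        bj = b[j]
        if not screen[j]:
            continue
        if active_only and bj == 0.0:
            continue
        if den[j] <= 0.0:
            continue
        num = 0.0
        for i in range(n):
            num += X[i, j] * w[i] * r[i]
        num = num / n + den[j] * bj
        bnew = _soft(num, lam) / den[j]
        d = bnew - bj
        if d != 0.0:
            b[j] = bnew
            for i in range(n):
                r[i] -= X[i, j] * d
            ad = abs(d)
            if ad > maxd:
                maxd = ad
    return maxd


@njit(cache=True)
def _intercept_step(w, r, b0):
    sw = 0.0
    swr = 0.0
    for i in range(w.shape[0]):
        sw += w[i]
        swr += w[i] * r[i]
    d = swr / sw
    for i in range(r.shape[0]):
        r[i] -= d
    return b0 + d, abs(d)


@njit(cache=True)
def _gradients(X, w, r):
    """g_j = (1/n) x_j' W r for every column."""
    n, p = X.shape
    g = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * w[i] * r[i]
        g[j] = s / n
    return g


@njit(cache=True)
def weighted_lasso(X, z, w, lam, lam_prev, tol, max_iter, b, b0):
    """Minimize (1/(2n)) sum w_i (z_i - b0 - x_i.b)^2 + lam |b|_1.

    ``b`` is modified in place (warm start in, solution out).  Returns
    (b0, n_sweeps, converged).  A "sweep" is one full pass over the
    working set; inner active-set passes are not counted.
    """
    n, p = X.shape
    den = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j] * w[i]
        den[j] = s / n
    r = np.empty(n)
    for i in range(n):
        f = b0
        for j in range(p):
            if b[j] != 0.0:
                f += X[i, j] * b[j]
        r[i] = z[i] - f

    # sequential strong rule at the warm-start point
    g = _gradients(X, w, r)
    thresh = 2.0 * lam - lam_prev
    screen = np.empty(p, dtype=np.bool_)
    for j in range(p):
        screen[j] = b[j] != 0.0 or abs(g[j]) >= thresh

    converged = False
    it = 0
    while it < max_iter:
        it += 1
        b0, d0 = _intercept_step(w, r, b0)
        maxd = _sweep(X, w, r, b, lam, den, screen, False)
        if maxd < tol and d0 < tol:
            # converged on the working set: verify KKT on all coordinates
            g = _gradients(X, w, r)
            nviol = 0
            for j in range(p):
                if not screen[j] and abs(g[j]) > lam:
                    screen[j] = True
                    nviol += 1
            if nviol == 0:
                converged = True
                break
            continue
        # polish on the active set before the next working-set pass
        inner = 0
        while inner < 1000:
            inner += 1
            b0, d0 = _intercept_step(w, r, b0)
            d = _sweep(X, w, r, b, lam, den, screen, True)
            if d < tol and d0 < tol:
                break
    return b0, it, converged


@njit(cache=True)
def _expit(u):
    if u >= 0.0:
        return 1.0 / (1.0 + np.exp(-u))
    e = np.exp(u)
    return e / (1.0 + e)


@njit(cache=True)
def logistic_lasso(X, y01, lam, lam_prev, tol, max_iter, max_outer, b, b0):
    """Proximal-Newton for (1/n) sum log(1+exp(-y f)) + lam |b|_1.

    At each outer step the logistic risk is expanded to second order at the
    current coefficients (IRLS weights clipped below at WEIGHT_FLOOR) and
    the penalized weighted least-squares subproblem is solved by coordinate
    descent.  ``b`` is modified in place.  Returns (b0, n_outer, converged).
    """
    n, p = X.shape
    w = np.empty(n)
    z = np.empty(n)
    bprev = np.empty(p)
    converged = False
    outer = 0
    while outer < max_outer:
        outer += 1
        b0prev = b0
        for j in range(p):
            bprev[j] = b[j]
        for i in range(n):
            f = b0
            for j in range(p):
                if b[j] != 0.0:
                    f += X[i, j] * b[j]
            pr = _expit(f)
            wi = pr * (1.0 - pr)
            if wi < WEIGHT_FLOOR:
                wi = WEIGHT_FLOOR
            w[i] = wi
            z[i] = f + (y01[i] - pr) / wi
        b0, _, _ = weighted_lasso(X, z, w, lam, lam_prev, tol, max_iter, b, b0)
        maxd = abs(b0 - b0prev)
        for j in range(p):
            d = abs(b[j] - bprev[j])
            if d > maxd:
                maxd = d
        if maxd < tol * 10.0:
            converged = True
            break
    return b0, outer, converged
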