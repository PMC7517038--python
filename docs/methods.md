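# Methods

## Generative model

All synthetic data follow the single-index binary model: rows of the
design are i.i.d. `N(0, H)` with the equicorrelated covariance
`H_jj = 1`, `H_jk = ρ` (default ρ = 0.5), and labels are
`Y = +1` with probability `η(x) = g(β₀ + β̊ᵀx)`, else `−1`.  The design
is realized by the one-factor decomposition
`X_ij = √ρ Z_i + √(1−ρ) W_ij`, which gives the equicorrelated law
exactly and makes any column subset of the design another equicorrelated
Gaussian — a property the oracle-only experiment exploits (see below).
`H` is positive definite for every ρ ∈ [0, 1) (eigenvalues `1−ρ` and
`1+(p−1)ρ`).

The study conditions fix the true coefficients at
`β = (1, ±1 × 10, 0, …, 0)` with signs drawn uniformly and *redrawn
independently in every replication* (replication r uses sign seed
`base_seed + r`, so runs are reproducible yet sign patterns vary).  Two
links are built in: the logistic CDF (Scenario 1 — well specified for the
logistic-loss fit) and `g(u) = arctan(u)/π + 1/2` (Scenario 2 — both fits
misspecified).  Custom callables are accepted everywhere a link tag is.

What the generator does *not* emulate: heavy-tailed or discrete
predictors, heteroscedastic designs, label noise beyond the Bernoulli
model, and dependence between observations.  Passing tests therefore
certify behaviour under a correctly sampled elliptical design, not
robustness to violations of it.

Labels are encoded {−1, +1} throughout; the delimited-file reader maps
{0, 1} input to {−1, +1} with a warning.  The Bayes risk
`R_B = E[min(η, 1−η)]` is estimated by Monte Carlo on the scalar index
(whose law `N(β₀, β̊ᵀHβ̊)` is known in closed form), m = 10⁶ draws by
default, with a reported standard error.

## Solvers

Both penalized problems use the 1/n empirical-risk convention with an
unpenalized intercept.  The quadratic loss `(1−yf)² = (y−f)²` reduces to
penalized least squares; its stationarity conditions carry the factor 2
from differentiating the square, so `λ_max = max_j |(2/n) x_jᵀ(y−ȳ)|`.
The logistic problem is solved by proximal Newton: a second-order
expansion at the current iterate (IRLS weights clipped below at 10⁻⁵)
followed by weighted coordinate descent, iterated to joint convergence.

Numerical choices:

* convergence is declared when the largest coefficient change in a sweep
  falls below `tol`; the default is 10⁻⁷ with up to 10⁵ sweeps.  The
  simulation harness uses `tol = 10⁻⁴` for its cross-validation paths —
  still tighter than the effective coefficient tolerance of the widely
  used coordinate-descent packages — because CV curves and selections are
  insensitive at that level while the saturated tail of a p ≫ n path
  converges slowly;
* sweeps run over a working set screened by the sequential strong rule
  (keep j when the gradient at the previous path point exceeds
  `2λ_i − λ_{i−1}`); after convergence the KKT conditions are checked on
  *all* coordinates and violators re-enter, so screening never changes
  the solution.  Standalone (non-path) fits disable screening;
* every converged fit carries a KKT certificate: for zero slopes
  `|∇_j| ≤ λ`, for active slopes `∇_j = −λ sign(b_j)`, both within slack
  `10·tol`; a regression test verifies screened path solutions against
  unscreened single fits;
* no internal standardization by default (the generative design already
  has unit variances); predictors from user files can be standardized
  upstream.

Cross-validation uses a seeded random partition into 10 folds, a shared
log-spaced grid of 100 λ values from `λ_max` down to `10⁻³ λ_max`, the
training loss φ itself as the held-out criterion, and the minimizer of
the mean CV curve ("lambda.min"; ties to the larger λ).  All folds
descend the path in lockstep with warm starts; the harness stops the
descent once the mean curve has not improved for 10 consecutive grid
points, which prunes the expensive saturated tail without affecting the
selected λ (regression-tested).  A fold left with a single class falls
back to intercept-only fits with a warning.

## Population targets

For the quadratic loss the population minimizer solves the normal
equations `H̃ b* = E[x̃(2η(x)−1)]` with `H̃ = diag(1, H)` known in closed
form; only the cross-moment is Monte Carlo (chunked, m = 10⁶ default).
A second, independent route through the one-dimensional index integral
(`b*` slopes = `γ β̊`) serves as a cross-check.  The logistic-loss
minimizer has no closed form and is *defined operationally* as the λ = 0
fit on a large synthetic sample; its error scale is estimated by a
half-sample split.  `γ` is computed from its defining ratio with the
denominator `β̊ᵀHβ̊ = (1−ρ)|β̊|² + ρ(Σβ̊_j)²` in closed form and the
numerator averaged over the exactly-Gaussian scalar index.

The Bernoulli KL distance uses the `0·log 0 = 0` convention and returns
+∞ for a degenerate second argument with mismatched first argument.  The
squared-error bound on the logistic approximation error,
`(2δ(1−δ))⁻¹ E[(η−η_log)²]`, is only valid when both probabilities lie in
`[δ, 1−δ]`; the caller chooses δ and the tests exercise the bound on a
weak-signal model where the hypothesis holds.

## Cone diagnostics

RE(ξ), K(ξ) and the CIFs are nonconvex ratio minimizations over the cone
`C(ξ)`; the returned value is a *certified upper bound*: the best vector
found over 256 seeded restarts (Gaussian on the support block, uniformly
scaled off-support block, plus the smallest eigenvectors of the Gram
matrix projected onto the cone) polished by Nelder–Mead on a penalized,
scale-free objective.  The certificate is returned, always lies in the
cone, and reproduces the value to 10⁻⁸.  For p+1 ≤ 3 an exhaustive
sphere-grid oracle (Fibonacci covering, ~4·10⁵ points) bounds the truth
within ~10⁻².  Monotonicity in ξ is available exactly by seeding the
larger-ξ search with the smaller-ξ certificate (`extra_starts`), since
the cones are nested.  Conventions: the cone constraint uses `T̃ = T∪{0}`
(with intercept) while K(ξ)'s normalization `|b_T|₁` excludes the
intercept; `q = ∞` takes `|T|^{1/q} → 1`.  Near-zero values (rank-deficient
designs) are returned as found; the infimum may be attained only in the
limit.

## Selection and metrics

Thresholding zeroes slopes with `|b̂_j| < δ` (intercept untouched).  TD
counts the raw Lasso support's overlap with the true support — no
thresholding — matching the threshold-free framing of the separation
metric; sep uses strict inequality against the largest irrelevant
|coefficient| (0 when all irrelevant coefficients vanish), so
`sep ≤ TD ≤ |T|` always.  Test accuracy predicts +1 on ties (`f = 0`).
The theory's threshold interval has unknown endpoints, so the recovery
experiment uses the pre-registered rule `λ = 0.5 √(log p / n)`,
`δ = |γ|/2` (half the smallest population slope magnitude, with |β_j| = 1
on the support) and additionally records the empirically valid interval
`(max_{k∉T}|b̂_k|, min_{j∈T}|b̂_j|]` per replication.

## Simulation harness

Per replication: draw signs, an n-point training set and a fresh
1000-point test set (regenerated every replication); fit both Lasso
estimators with 10-fold CV and the oracle; record TD, sep, pred.  The
oracle maximizes the exact likelihood `Σ log g(±f)` over the |T|+1 free
parameters by damped Newton (Levenberg regularization, backtracking line
search, probabilities clipped to [10⁻⁶, 1−10⁻⁶]) using the analytic
first/second link derivatives, with a quasi-Newton fallback for custom
links or non-convergence.  A failed replication is redrawn with a shifted
seed; more than 1% failures aborts.

The oracle-only runner generates *only the relevant columns* of the
design: because any column subset of an equicorrelated Gaussian is again
equicorrelated Gaussian and the oracle never touches irrelevant columns,
the law of its accuracy is identical to a full-design run at any ambient
p, at a tiny fraction of the cost.

Problem sizes: the package defaults to the study's 300 replications;
the test suite and the acceptance script run scaled-down counts (60 at
n = 100, 6–20 at the larger settings, 100–200 where fits are cheap),
chosen so that the Monte-Carlo standard errors of the compared means stay
well inside the stated tolerances on a single CPU.  Timing comparisons
between the two solvers are deliberately not an output (hardware
dependent).

## Known limitations

* The cone functionals are upper bounds; no lower-bound certificate
  (e.g. a semidefinite relaxation) is provided.
* The logistic population minimizer inherits Monte-Carlo error from its
  defining sample; quantities derived from it (KL approximation error)
  carry that error.
* The theory's finite-sample bounds contain unspecified universal
  constants, so the package evaluates their *components* (margin
  probability, approximation errors, cone factors) and checks the
  qualitative rates empirically rather than evaluating the bounds as
  numbers.
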