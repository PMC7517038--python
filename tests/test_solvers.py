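"""Solver correctness: analytic limits, external cross-checks, brute force,
KKT certificates, path behaviour, cross-validation."""

import warnings

import numpy as np
import pytest

from misclasso import (
    Dataset,
    cross_validate,
    fit_cv,
    fit_lasso,
    lambda_max,
    predict_labels,
    soft_threshold,
)
from misclasso.solvers import (
    check_kkt,
    fit_path,
    kkt_residuals,
    lambda_grid,
    penalized_objective,
)

from conftest import tiny_dataset


class TestSoftThreshold:
    @pytest.mark.parametrize("z,t,expected", [
        (0.0, 1.0, 0.0),
        (3.0, 1.0, 2.0),
        (-3.0, 1.0, -2.0),
        (0.5, 1.0, 0.0),
        (2.0, 0.0, 2.0),
    ])
    def test_values(self, z, t, expected):
        assert soft_threshold(z, t) == expected

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.5)


class TestUnpenalizedLimits:
    def test_quadratic_lam0_equals_ols(self, small_logistic_data):
        ds, _ = small_logistic_data
        fit = fit_lasso(ds, "quadratic", lam=0.0)
        Xt = np.column_stack([np.ones(ds.n), ds.X])
        ols, *_ = np.linalg.lstsq(Xt, ds.y, rcond=None)
        assert np.allclose(fit.coef, ols, atol=1e-6)

    def test_logistic_lam0_equals_mle(self, small_logistic_data):
        import statsmodels.api as sm

        ds, _ = small_logistic_data
        fit = fit_lasso(ds, "logistic", lam=0.0, tol=1e-8)
        res = sm.Logit((ds.y + 1) / 2, sm.add_constant(ds.X)).fit(disp=0)
        assert np.allclose(fit.coef, res.params, atol=1e-4)

    def test_complete_separation_flagged(self):
        X = np.linspace(-1, 1, 20).reshape(-1, 1)
        y = np.where(X[:, 0] > 0, 1.0, -1.0)
        ds = Dataset(X=X, y=y)
        with pytest.warns(UserWarning, match="did not converge"):
            fit = fit_lasso(ds, "logistic", lam=0.0)
        assert not fit.converged


class TestFullShrinkage:
    @pytest.mark.parametrize("loss", ["quadratic", "logistic"])
    def test_above_lambda_max_gives_null_model(self, loss):
        ds, _ = tiny_dataset(n=50, p=8, seed=3)
        lam = 1.01 * lambda_max(ds, loss)
        fit = fit_lasso(ds, loss, lam)
        assert np.all(fit.slopes == 0.0)
        if loss == "quadratic":
            assert np.isclose(fit.intercept, ds.y.mean())
        else:
            npos = np.sum(ds.y == 1.0)
            assert np.isclose(fit.intercept, np.log(npos / (ds.n - npos)), atol=1e-6)

    def test_constant_labels_finite_lambda_max(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        ds = Dataset(X=X, y=np.ones(10))
        assert np.isfinite(lambda_max(ds, "quadratic"))

    def test_single_predictor_closed_form(self):
        # For one centered predictor, lambda_max = |(2/n) x.(y - ybar)|
        x = np.array([1.0, -1.0, 2.0, -2.0])
        y = np.array([1.0, -1.0, 1.0, -1.0])
        ds = Dataset(X=x.reshape(-1, 1), y=y)
        assert np.isclose(lambda_max(ds, "quadratic"), abs(2 / 4 * x @ y))


def _lattice_minimize(ds, loss, lam, step=0.05, lo=-3.0, hi=3.0):
    """Exhaustive lattice minimization of the penalized objective over
    [lo, hi]^3 (intercept plus two slopes), vectorized over lattice points."""
    g = np.arange(lo, hi + step / 2, step)
    B = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1).reshape(-1, 3)
    F = B[:, 0] + ds.X @ B[:, 1:].T  # n x n_points index values
    t = ds.y[:, None] * F
    if loss == "quadratic":
        risk = np.mean((1.0 - t) ** 2, axis=0)
    else:
        risk = np.mean(np.logaddexp(0.0, -t), axis=0)
    obj = risk + lam * np.abs(B[:, 1:]).sum(axis=1)
    i = int(np.argmin(obj))
    return B[i], float(obj[i])


class TestBruteForceOracle:
    """Both solvers against exhaustive lattice search on p=2 problems."""

    @pytest.mark.parametrize("seed", range(20))
    def test_quadratic_matches_lattice(self, seed):
        ds, _ = tiny_dataset(n=6, p=2, seed=100 + seed)
        lam = 0.1
        fit = fit_lasso(ds, "quadratic", lam)
        step = 0.05
        arg, best = _lattice_minimize(ds, "quadratic", lam, step)
        assert np.all(np.abs(fit.coef - arg) <= step + 1e-9)
        assert fit.objective <= best + 1e-9

    @pytest.mark.parametrize("seed", range(20))
    def test_logistic_objective_below_lattice_minimum(self, seed):
        ds, _ = tiny_dataset(n=8, p=2, seed=200 + seed)
        lam = 0.05
        fit = fit_lasso(ds, "logistic", lam, tol=1e-8)
        arg, best = _lattice_minimize(ds, "logistic", lam, 0.05)
        # the logistic objective is flat near its minimum, so only the
        # objective value is compared at lattice resolution
        assert fit.objective <= best + 1e-5


class TestExternalCrossChecks:
    def test_quadratic_matches_sklearn_lasso(self):
        # identical problem up to scaling: alpha = lam / 2
        from sklearn.linear_model import Lasso

        ds, _ = tiny_dataset(n=80, p=15, seed=4)
        lam = 0.1
        fit = fit_lasso(ds, "quadratic", lam)
        sk = Lasso(alpha=lam / 2, tol=1e-10, max_iter=10**5).fit(ds.X, ds.y)
        assert np.allclose(fit.slopes, sk.coef_, atol=1e-6)
        assert np.isclose(fit.intercept, sk.intercept_, atol=1e-6)

    def test_logistic_matches_sklearn_saga(self):
        from sklearn.linear_model import LogisticRegression

        ds, _ = tiny_dataset(n=80, p=15, seed=5)
        lam = 0.05
        fit = fit_lasso(ds, "logistic", lam, tol=1e-8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sk = LogisticRegression(penalty="l1", C=1.0 / (ds.n * lam),
                                    solver="saga", tol=1e-10,
                                    max_iter=10**5).fit(ds.X, ds.y)
        assert np.allclose(fit.slopes, sk.coef_[0], atol=1e-5)
        assert np.isclose(fit.intercept, sk.intercept_[0], atol=1e-5)


class TestKKT:
    @pytest.mark.parametrize("loss", ["quadratic", "logistic"])
    @pytest.mark.parametrize("lam", [0.02, 0.1, 0.3])
    def test_certificate_holds_on_converged_fits(self, loss, lam):
        ds, _ = tiny_dataset(n=60, p=12, seed=6)
        fit = fit_lasso(ds, loss, lam)
        assert fit.converged
        assert check_kkt(fit, ds)

    def test_objective_recomputable(self):
        ds, _ = tiny_dataset(n=40, p=5, seed=7)
        fit = fit_lasso(ds, "quadratic", 0.05)
        assert np.isclose(fit.objective,
                          penalized_objective(fit.coef, ds, "quadratic", 0.05),
                          atol=1e-8)

    def test_screened_fit_matches_unscreened(self):
        """The strong-rule screen must not change the path solutions."""
        ds, _ = tiny_dataset(n=50, p=30, seed=8)
        grid = lambda_grid(ds, "quadratic", 20)
        path = fit_path(ds, "quadratic", grid)  # screened, warm-started
        for i in (5, 12, 19):
            direct = fit_lasso(ds, "quadratic", grid[i])  # unscreened
            assert np.allclose(path[i], direct.coef, atol=1e-5)

    def test_non_finite_data_rejected(self):
        X = np.ones((4, 2))
        X[0, 0] = np.nan
        bad = Dataset(X=X, y=np.array([1.0, -1, 1, -1]))
        with pytest.raises(ValueError, match="non-finite"):
            fit_lasso(bad, "quadratic", 0.1)


class TestPath:
    def test_coefficients_continuous_along_path(self):
        ds, _ = tiny_dataset(n=60, p=10, seed=9)
        grid = lambda_grid(ds, "quadratic", 50)
        path = fit_path(ds, "quadratic", grid)
        jumps = np.max(np.abs(np.diff(path, axis=0)), axis=1)
        # adjacent grid points differ by a 7% lambda step; coefficient moves
        # are small and comparable to the lambda increments
        assert jumps.max() < 5 * np.max(-np.diff(grid))

    def test_path_starts_null(self):
        ds, _ = tiny_dataset(n=60, p=10, seed=10)
        grid = lambda_grid(ds, "logistic", 10)
        path = fit_path(ds, "logistic", grid)
        # the path starts exactly at lambda_max, where roundoff can leave
        # one coordinate at machine-epsilon scale
        assert np.allclose(path[0, 1:], 0.0, atol=1e-10)


class TestCrossValidation:
    def test_deterministic_given_seed(self):
        ds, _ = tiny_dataset(n=60, p=10, seed=11)
        a = cross_validate(ds, "quadratic", n_folds=5, grid_size=30, seed=3)
        b = cross_validate(ds, "quadratic", n_folds=5, grid_size=30, seed=3)
        assert np.array_equal(a.lam_grid, b.lam_grid)
        assert np.array_equal(a.cv_loss, b.cv_loss)
        assert a.lam_selected == b.lam_selected

    def test_selected_lambda_in_grid(self):
        ds, _ = tiny_dataset(n=60, p=10, seed=12)
        cv = cross_validate(ds, "logistic", n_folds=5, grid_size=25, seed=4)
        assert cv.lam_selected in cv.lam_grid
        assert cv.cv_loss.shape == cv.lam_grid.shape

    def test_pure_noise_selects_heavy_penalty(self):
        """With no signal, CV picks a large lambda and a near-empty model
        in the majority of seeds."""
        top_third = 0
        small_support = 0
        for seed in range(5):
            ds, _ = tiny_dataset(n=80, p=20, seed=300 + seed, k=0)
            fit, cv = fit_cv(ds, "quadratic", n_folds=5, grid_size=30,
                             seed=seed, tol=1e-5)
            rank = np.searchsorted(-cv.lam_grid, -fit.lam)
            top_third += rank < 10
            small_support += fit.support.size <= 4
        assert top_third >= 3
        assert small_support >= 3

    def test_strong_signal_screens_true_support(self):
        hits = 0
        for seed in range(3):
            ds, spec = tiny_dataset(n=300, p=5, seed=400 + seed, k=2)
            fit, _ = fit_cv(ds, "quadratic", n_folds=5, grid_size=30,
                            seed=seed, tol=1e-5)
            hits += set(spec.support) <= set(fit.support)
        assert hits >= 2

    def test_early_stopping_truncates_but_keeps_selection(self):
        ds, _ = tiny_dataset(n=80, p=20, seed=13, k=3)
        full = cross_validate(ds, "quadratic", n_folds=5, grid_size=40, seed=5)
        trunc = cross_validate(ds, "quadratic", n_folds=5, grid_size=40, seed=5,
                               patience=8)
        assert trunc.lam_grid.size <= full.lam_grid.size
        assert trunc.lam_selected == full.lam_selected


class TestPredictLabels:
    def test_zero_coef_predicts_plus_one(self):
        X = np.random.default_rng(0).standard_normal((5, 3))
        assert np.all(predict_labels(np.zeros(4), X) == 1.0)

    def test_sign_rule(self):
        assert predict_labels(np.array([0.0, 1.0]), np.array([[-2.0]]))[0] == -1.0

    def test_antisymmetry_off_ties(self):
        rng = np.random.default_rng(1)
        coef = rng.standard_normal(4)
        X = rng.standard_normal((50, 3))
        f = coef[0] + X @ coef[1:]
        strict = f != 0.0
        a = predict_labels(coef, X)
        b = predict_labels(-coef, X)
        assert np.all(a[strict] == -b[strict])
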