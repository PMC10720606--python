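"""Surrogate loss derivatives and the two penalized solvers."""

import numpy as np
import pytest
from scipy.optimize import minimize

from pearlitr.solver import (
    SolverOptions,
    make_lambda_grid,
    select_lambda,
    solve_decorrelation_lasso,
    solve_penalized_surrogate,
    surrogate_derivatives,
    surrogate_objective,
)


class TestSurrogateDerivatives:
    def test_values_at_zero(self):
        f, g, h = surrogate_derivatives(0.0)
        assert np.isclose(f, np.log(2.0))
        assert g == -0.5
        assert np.isclose(h, 0.25)

    def test_tail_behavior(self):
        t = np.array([5.0, 10.0, 50.0, 700.0])
        f, g, h = surrogate_derivatives(t)
        assert np.all(np.diff(f) < 0) and f[-1] < 1e-100  # loss decays to 0
        assert np.all(np.abs(g) < 1e-2) and np.all(h < 1e-2)
        # numerically stable for very negative margins too
        f_neg, g_neg, _ = surrogate_derivatives(-700.0)
        assert np.isfinite(f_neg) and np.isclose(g_neg, -1.0)

    def test_second_derivative_by_finite_differences(self):
        eps = 1e-5
        for t in (-3.0, -1.0, 0.0, 1.0, 3.0):
            _, _, h = surrogate_derivatives(t)
            _, g_hi, _ = surrogate_derivatives(t + eps)
            _, g_lo, _ = surrogate_derivatives(t - eps)
            assert abs(h - (g_hi - g_lo) / (2 * eps)) < 1e-6

    def test_convexity_conditions(self, rng):
        # bounded negative slope at 0 and strictly positive curvature
        t = rng.uniform(-6, 6, 200)
        _, g, h = surrogate_derivatives(t)
        assert np.all(g > -1.0) and np.all(g < 0.0)
        assert np.all(h > 0.0) and np.all(h <= 0.25)


def _scipy_l1_oracle(obj_smooth, lam, dim, rng, restarts=3):
    """Minimize smooth(beta) + lam*||beta||_1 via the split beta = u - v, u,v >= 0."""

    def obj(uv):
        return obj_smooth(uv[:dim] - uv[dim:]) + lam * uv.sum()

    best = np.inf
    for _ in range(restarts):
        x0 = np.abs(rng.standard_normal(2 * dim)) * 0.1
        res = minimize(obj, x0, method="L-BFGS-B", bounds=[(0, None)] * (2 * dim),
                       options=dict(maxiter=3000, ftol=1e-14, gtol=1e-10))
        best = min(best, res.fun)
    return best


class TestPenalizedSurrogate:
    def test_lambda_above_max_gives_exact_zero(self, rng):
        n, p = 40, 6
        X = rng.standard_normal((n, p))
        op, om = rng.gamma(2, 1, n), rng.gamma(2, 1, n)
        g0 = np.abs(X.T @ (-0.5 * (op - om)) / n).max()
        fit = solve_penalized_surrogate(X, op, om, 1.5 * g0)
        assert np.all(fit.beta == 0.0) and fit.converged

    def test_symmetric_problem_gives_zero(self):
        X = np.array([[1.0], [-1.0]])
        fit = solve_penalized_surrogate(X, np.ones(2), np.ones(2), 0.01)
        assert np.all(fit.beta == 0.0)

    def test_all_zero_weights_degenerate(self):
        X = np.eye(3)
        fit = solve_penalized_surrogate(X, np.zeros(3), np.zeros(3), 0.1)
        assert np.all(fit.beta == 0.0) and fit.converged and fit.objective == 0.0

    def test_descent_and_objective_consistency(self, rng):
        n, p = 60, 4
        X = rng.standard_normal((n, p))
        op, om = rng.gamma(2, 1, n), rng.gamma(1, 1, n)
        fit = solve_penalized_surrogate(X, op, om, 0.05)
        at_zero = surrogate_objective(np.zeros(p), X, op, om, 0.05)
        assert fit.objective <= at_zero + 1e-12
        assert np.isclose(fit.objective,
                          surrogate_objective(fit.beta, X, op, om, 0.05))

    def test_monotone_regularization_path(self, rng):
        n, p = 80, 10
        X = rng.standard_normal((n, p))
        op = rng.gamma(2, 1, n) * (1 + (X[:, 0] > 0))
        om = rng.gamma(2, 1, n)
        nnz = []
        for lam in make_lambda_grid(0.5, 12, 0.005):
            nnz.append(int(np.count_nonzero(
                solve_penalized_surrogate(X, op, om, lam).beta)))
        assert all(a <= b for a, b in zip(nnz, nnz[1:]))  # descending lambda

    def test_matches_convex_oracle(self, rng):
        n, p = 60, 3
        X = rng.standard_normal((n, p))
        # scenario-like weights: heavier when the first covariate is positive
        op = rng.gamma(2, 1, n) * (1.0 + (X[:, 0] > 0))
        om = rng.gamma(2, 1, n)
        lam = 0.05
        fit = solve_penalized_surrogate(X, op, om, lam)
        oracle = _scipy_l1_oracle(
            lambda b: surrogate_objective(b, X, op, om, 0.0), lam, p, rng)
        assert fit.objective <= oracle + 1e-6

    def test_input_validation(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError):
            solve_penalized_surrogate(X, np.ones(10), np.ones(10), -0.1)
        with pytest.raises(ValueError):
            solve_penalized_surrogate(X, np.full(10, np.nan), np.ones(10), 0.1)
        with pytest.raises(ValueError):
            solve_penalized_surrogate(X, -np.ones(10), np.ones(10), 0.1)


class TestDecorrelationLasso:
    def test_huge_penalty_zeroes_solution(self, rng):
        X = rng.standard_normal((50, 5))
        fit = solve_decorrelation_lasso(X, 2, np.ones(50), 1e6)
        assert np.all(fit.beta == 0.0)

    def test_duplicate_column_perfect_projection(self, rng):
        n = 60
        X = rng.standard_normal((n, 4))
        X[:, 3] = X[:, 1]  # exact copy of the target column
        fit = solve_decorrelation_lasso(X, 1, np.ones(n), 1e-4)
        w = fit.beta  # columns (0, 2, 3) regressing X[:,1]
        assert abs(w[2] - 1.0) < 0.05
        resid = X[:, 1] - np.delete(X, 1, 1) @ w
        assert np.mean(resid**2) < 1e-3

    def test_orthonormal_design_soft_threshold(self, rng):
        # Z'Z = n I and constant weights c: w_l = soft((Z'y)_l / n, lam/(2c))
        n, q = 64, 5
        Q, _ = np.linalg.qr(rng.standard_normal((n, q + 1)))
        Z = np.sqrt(n) * Q[:, :q]
        y = Q[:, q] * 2.0 + Z[:, 0] / np.sqrt(n) * 1.5
        X = np.column_stack([y, Z])
        c, lam = 0.7, 0.08
        fit = solve_decorrelation_lasso(X, 0, np.full(n, c), lam)
        rho = Z.T @ y / n
        expected = np.sign(rho) * np.maximum(np.abs(rho) - lam / (2 * c), 0.0)
        np.testing.assert_allclose(fit.beta, expected, atol=1e-6)

    def test_matches_convex_oracle(self, rng):
        n, p = 80, 5
        X = rng.standard_normal((n, p))
        h = rng.gamma(2, 0.25, n)
        lam = 0.02
        fit = solve_decorrelation_lasso(X, 3, h, lam)
        Z, y = np.delete(X, 3, 1), X[:, 3]
        oracle = _scipy_l1_oracle(
            lambda w: float(np.mean(h * (y - Z @ w) ** 2)), lam, p - 1, rng)
        assert fit.objective <= oracle + 1e-6

    def test_zero_weights_rejected(self, rng):
        with pytest.raises(ValueError, match="curvature"):
            solve_decorrelation_lasso(rng.standard_normal((10, 3)), 0,
                                      np.zeros(10), 0.1)


class TestSelectLambda:
    def test_single_element_grid(self, rng):
        X = rng.standard_normal((30, 3))
        lam = select_lambda(X, np.ones(30), np.ones(30), grid=np.array([0.3]))
        assert lam == 0.3

    def test_returned_value_is_grid_member(self, rng):
        X = rng.standard_normal((60, 4))
        op = rng.gamma(2, 1, 60)
        om = rng.gamma(2, 1, 60)
        grid = np.array([0.01, 0.05, 0.2, 1.0])
        lam = select_lambda(X, op, om, grid=grid, cv_folds=3, seed=1)
        assert lam in grid

    def test_cv_prefers_informative_penalty(self):
        # strong scenario-like signal: the trivializing penalty loses CV
        from pearlitr.simulate import ScenarioSpec, generate_scenario
        from pearlitr.aipw import aipw_weights

        spec = ScenarioSpec("I", n=2000, p=20, xi=0.7, seed=5)
        data = generate_scenario(spec)
        w = aipw_weights(data.Y, data.A, spec.propensity(data.X),
                         spec.outcome_mean(data.X, 1), spec.outcome_mean(data.X, -1))
        g0 = np.abs(data.X.T @ (-0.5 * (w.Omega_plus - w.Omega_minus)) / spec.n).max()
        grid = np.array([0.02 * g0, 2.0 * g0])  # informative vs trivializing
        lam = select_lambda(data.X, w.Omega_plus, w.Omega_minus,
                            grid=grid, cv_folds=3, seed=2)
        assert lam == grid[0]

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="nonempty"):
            select_lambda(rng.standard_normal((20, 2)), np.ones(20), np.ones(20),
                          grid=np.array([]))
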