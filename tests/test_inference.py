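"""De-correlated score construction, pooling identities, and the test table."""

import numpy as np
import pytest

from pearlitr.config import LambdaConfig, NuisanceConfig, PearlConfig
from pearlitr.estimator import fit_pearl
from pearlitr.inference import fold_score, infer_coordinate
from pearlitr.inference import test_table as coef_table
from pearlitr.simulate import Dataset, ScenarioSpec, generate_scenario
from pearlitr.solver import loss_gradient_scalars


@pytest.fixture
def small_fit():
    spec = ScenarioSpec("I", n=200, p=4, xi=0.7, seed=13)
    data = generate_scenario(spec)
    nuis = NuisanceConfig(
        propensity_fn=spec.propensity,
        outcome_fns=(lambda X: spec.outcome_mean(X, 1),
                     lambda X: spec.outcome_mean(X, -1)),
    )
    cfg = PearlConfig(K=2, seed=2, nuisance=nuis,
                      lam=LambdaConfig(grid_size=6, cv_folds=3),
                      lam_tilde=LambdaConfig(grid_size=6, cv_folds=3))
    return spec, data, fit_pearl(data, cfg)


class TestFoldScore:
    def test_matches_straight_line_reimplementation(self, small_fit):
        # independent elementwise recomputation of the displayed fold average
        _, _, fit = small_fit
        lam_tilde = 0.05
        for k in (0, 1):
            fs = fold_score(fit, k, j=2, lambda_tilde=lam_tilde)
            ff = fit.folds[k]
            Xk = fit.X[ff.index]
            op, om = ff.weights.Omega_plus, ff.weights.Omega_minus
            beta_null = ff.beta.copy()
            beta_null[2] = 0.0
            n_k = len(ff.index)
            s_oracle = 0.0
            for i in range(n_k):
                zi = float(Xk[i] @ beta_null)
                grad_i = op[i] * (-1.0 / (1.0 + np.exp(zi))) - om[i] * (
                    -1.0 / (1.0 + np.exp(-zi)))
                resid_i = Xk[i, 2] - np.delete(Xk[i], 2) @ fs.w_hat
                s_oracle += grad_i * resid_i
            s_oracle /= n_k
            assert abs(fs.S_null - s_oracle) < 1e-10

    def test_huge_penalty_reduces_to_plain_score(self, small_fit):
        _, _, fit = small_fit
        fs = fold_score(fit, 0, j=1, lambda_tilde=1e8)
        assert np.all(fs.w_hat == 0.0)
        ff = fit.folds[0]
        Xk = fit.X[ff.index]
        beta_null = ff.beta.copy()
        beta_null[1] = 0.0
        plain = float(np.mean(
            loss_gradient_scalars(Xk @ beta_null, ff.weights.Omega_plus,
                                  ff.weights.Omega_minus) * Xk[:, 1]))
        assert np.isclose(fs.S_null, plain, atol=1e-12)

    def test_duplicate_column_annihilates_score(self):
        spec = ScenarioSpec("I", n=150, p=5, xi=0.7, seed=23)
        data = generate_scenario(spec)
        X = data.X.copy()
        X[:, 4] = X[:, 1]  # exact duplicate of coordinate 1
        dup = Dataset(X=X, A=data.A, Y=data.Y)
        nuis = NuisanceConfig(propensity_fn=spec.propensity,
                              outcome_fns=(lambda X: np.zeros(len(X)),) * 2)
        cfg = PearlConfig(K=2, seed=3, nuisance=nuis,
                          lam=LambdaConfig(fixed=0.1),
                          lam_tilde=LambdaConfig(fixed=1e-4))
        fit = fit_pearl(dup, cfg)
        fs = fold_score(fit, 0, j=1, lambda_tilde=1e-4)
        assert abs(fs.S_null) < 0.02
        assert abs(fs.I_info) < 0.05


class TestPooled:
    def test_pooling_linearity_exact(self, small_fit):
        _, _, fit = small_fit
        res = infer_coordinate(fit, 3, lambda_tilde=0.05)
        assert res.S == np.mean([fs.S_null for fs in res.fold_scores])
        one_steps = [fit.folds[fs.k].beta[3] - fs.S_full / fs.I_info
                     for fs in res.fold_scores]
        assert np.isclose(res.beta_tilde, np.mean(one_steps), atol=1e-14)

    def test_ci_width_algebra(self, small_fit):
        from scipy.stats import norm

        _, _, fit = small_fit
        res = infer_coordinate(fit, 0, lambda_tilde=0.05, alpha=0.1)
        lo, hi = res.ci
        n = fit.plan.n
        expected = 2 * norm.ppf(0.95) * np.sqrt(res.sigma2) / (
            np.sqrt(n) * abs(res.I_info))
        assert np.isclose(hi - lo, expected, rtol=1e-12)
        assert np.isclose((hi + lo) / 2, res.beta_tilde, atol=1e-12)

    def test_zero_score_means_no_correction(self, small_fit):
        # algebraic fixed point: when every fold score at the fold coefficients
        # vanishes, the one-step estimate equals the penalized estimate
        _, _, fit = small_fit
        res = infer_coordinate(fit, 3, lambda_tilde=0.05)
        for fs in res.fold_scores:
            fs.S_full = 0.0
        one_steps = [fit.folds[fs.k].beta[3] - fs.S_full / fs.I_info
                     for fs in res.fold_scores]
        assert np.isclose(np.mean(one_steps),
                          np.mean([fit.folds[k].beta[3] for k in range(2)]))

    def test_degenerate_zero_outcome_flagged(self):
        spec = ScenarioSpec("I", n=120, p=4, xi=0.7, seed=31)
        data = generate_scenario(spec)
        silent = Dataset(X=data.X, A=data.A, Y=np.zeros(data.n))
        nuis = NuisanceConfig(propensity_fn=lambda X: np.full(len(X), 0.5),
                              outcome_fns=(lambda X: np.zeros(len(X)),) * 2)
        cfg = PearlConfig(K=2, seed=1, nuisance=nuis,
                          lam=LambdaConfig(fixed=0.1),
                          lam_tilde=LambdaConfig(fixed=0.1))
        fit = fit_pearl(silent, cfg)
        assert np.all(fit.beta == 0.0)
        res = infer_coordinate(fit, 2)
        assert res.degenerate and np.isnan(res.p_value)


class TestTable:
    def test_columns_and_singleton_fdr(self, small_fit):
        _, _, fit = small_fit
        table = coef_table(fit, [2], alpha=0.05, fdr=True, lambda_tilde=0.05)
        assert list(table.columns[:8]) == [
            "j", "beta_hat", "beta_tilde", "se", "z", "p", "ci_lo", "ci_hi"]
        assert np.isclose(table["q"].iloc[0], table["p"].iloc[0])

    def test_bh_adjustment_hand_computed(self, small_fit):
        _, _, fit = small_fit
        table = coef_table(fit, [0, 1, 2, 3], fdr=True, lambda_tilde=0.05)
        p = table["p"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        staged = p[order] * m / np.arange(1, m + 1)
        expected_sorted = np.minimum.accumulate(staged[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(expected_sorted, 1.0)
        np.testing.assert_allclose(table["q"].to_numpy(), expected, rtol=1e-12)

    def test_empty_coordinate_set_rejected(self, small_fit):
        _, _, fit = small_fit
        with pytest.raises(ValueError, match="nonempty"):
            coef_table(fit, [])
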