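"""Split-and-pooled de-correlated score inference for single rule coefficients.

For coordinate j and fold k (nuisances from the fold's complement already
folded into the weights):

* a weighted-lasso projection of X_j on the remaining covariates, with per-row
  curvature weights evaluated at the fold coefficients, yields w_hat_j(k);
* the de-correlated score is the fold average of
  grad-factor(beta) * (X_j - X_-j' w_hat_j(k)), evaluated at beta_null
  (fold coefficients with coordinate j zeroed) for testing, and at the fold
  coefficients themselves for the one-step correction;
* the partial information is the fold average of
  curvature * X_j * (X_j - X_-j' w_hat_j(k)).

Pooled across folds: S_j (mean of fold scores), the one-step coefficient
beta_tilde_j (mean of fold one-step corrections), the variance estimate
sigma_j^2 (pooled empirical second moment of the per-row de-correlated score
terms), the standardized statistic z = sqrt(n) S_j / sigma_j with a two-sided
normal p-value, and the symmetric interval
beta_tilde_j +/- z_{1-alpha/2} sigma_j / (sqrt(n) I_j|-j).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .estimator import PEARLFit
from .solver import (
    SolverOptions,
    loss_gradient_scalars,
    loss_hessian_scalars,
    select_lambda_tilde,
    solve_decorrelation_lasso,
)

__all__ = [
    "FoldScore",
    "CoordinateInference",
    "fold_score",
    "pooled_test",
    "one_step_ci",
    "infer_coordinate",
    "test_table",
]

_INFO_TOL = 1e-8   # |I_j|-j| below this marks the fold's one-step as unstable
_VAR_TOL = 1e-12   # sigma^2 below this marks the coordinate as degenerate


@dataclass
class FoldScore:
    """Fold-level ingredients of the de-correlated score for one coordinate."""

    k: int
    j: int
    w_hat: np.ndarray
    lam_tilde: float
    S_null: float            # score at beta with coordinate j zeroed (test)
    S_full: float            # score at the fold coefficients (one-step)
    I_info: float            # partial information I_j|-j
    score_terms_null: np.ndarray
    score_terms_full: np.ndarray


@dataclass
class CoordinateInference:
    """Pooled test and one-step interval for a single coefficient."""

    j: int
    alpha: float
    fold_scores: list[FoldScore] = field(repr=False, default_factory=list)
    S: float = np.nan
    sigma2: float = np.nan
    I_info: float = np.nan
    beta_hat: float = np.nan       # pooled penalized estimate
    beta_tilde: float = np.nan     # pooled one-step estimate
    z: float = np.nan
    p_value: float = np.nan
    ci: tuple[float, float] = (np.nan, np.nan)
    degenerate: bool = False
    unstable: bool = False

    @property
    def se(self) -> float:
        """Standard error of the one-step estimate."""
        if self.degenerate or self.unstable:
            return np.nan
        n = sum(len(fs.score_terms_null) for fs in self.fold_scores)
        return float(np.sqrt(self.sigma2) / (np.sqrt(n) * abs(self.I_info)))


def fold_score(
    fit: PEARLFit,
    k: int,
    j: int,
    lambda_tilde: float | None = None,
    options: SolverOptions | None = None,
) -> FoldScore:
    """De-correlated score pieces for coordinate j on fold k.

    ``lambda_tilde=None`` selects the de-correlation penalty by weighted-lasso
    cross-validation on the fold's rows.
    """
    ff = fit.folds[k]
    Xk = fit.X[ff.index]
    op, om = ff.weights.Omega_plus, ff.weights.Omega_minus
    beta = ff.beta
    z = Xk @ beta
    h = loss_hessian_scalars(z, op, om)
    cfg = fit.config
    options = options or cfg.solver
    if not np.any(h > 0):
        # zero-signal degenerate data: every score term vanishes identically
        zeros = np.zeros(len(ff.index))
        return FoldScore(k=k, j=j, w_hat=np.zeros(Xk.shape[1] - 1),
                         lam_tilde=float(lambda_tilde or 0.0),
                         S_null=0.0, S_full=0.0, I_info=0.0,
                         score_terms_null=zeros, score_terms_full=zeros)
    if lambda_tilde is None and cfg.lam_tilde.fixed is not None:
        lambda_tilde = float(cfg.lam_tilde.fixed)
    if lambda_tilde is None:
        lambda_tilde = select_lambda_tilde(
            Xk, j, h,
            cv_folds=cfg.lam_tilde.cv_folds,
            seed=(cfg.seed * 1_000_003 + 7919 * k + j) % 2**31,
            grid_size=cfg.lam_tilde.grid_size,
            grid_eps=cfg.lam_tilde.grid_eps,
            options=cfg.cv_solver_options(cfg.lam_tilde),
        )
    try:
        w_fit = solve_decorrelation_lasso(Xk, j, h, lambda_tilde, options=options)
    except Exception as err:
        raise RuntimeError(
            f"de-correlation solve failed for fold {k}, coordinate {j}: {err}"
        ) from err
    resid = Xk[:, j] - np.delete(Xk, j, axis=1) @ w_fit.beta

    z_null = z - Xk[:, j] * beta[j]
    s_null = loss_gradient_scalars(z_null, op, om)
    s_full = loss_gradient_scalars(z, op, om)
    terms_null = s_null * resid
    terms_full = s_full * resid
    return FoldScore(
        k=k, j=j, w_hat=w_fit.beta, lam_tilde=float(lambda_tilde),
        S_null=float(terms_null.mean()), S_full=float(terms_full.mean()),
        I_info=float(np.mean(h * Xk[:, j] * resid)),
        score_terms_null=terms_null, score_terms_full=terms_full,
    )


def infer_coordinate(
    fit: PEARLFit,
    j: int,
    lambda_tilde: float | None = None,
    alpha: float = 0.05,
) -> CoordinateInference:
    """Pooled de-correlated score test and one-step confidence interval for beta_j."""
    scores = [fold_score(fit, k, j, lambda_tilde) for k in range(fit.plan.K)]
    n = fit.plan.n
    out = CoordinateInference(j=j, alpha=alpha, fold_scores=scores,
                              beta_hat=float(fit.beta[j]))
    out.S = float(np.mean([fs.S_null for fs in scores]))
    out.sigma2 = float(np.mean([np.mean(fs.score_terms_null**2) for fs in scores]))
    out.I_info = float(np.mean([fs.I_info for fs in scores]))

    if out.sigma2 <= _VAR_TOL:
        out.degenerate = True
        return out
    sigma = np.sqrt(out.sigma2)
    out.z = float(np.sqrt(n) * out.S / sigma)
    out.p_value = float(2.0 * norm.sf(abs(out.z)))

    if any(abs(fs.I_info) < _INFO_TOL for fs in scores):
        out.unstable = True
        return out
    one_steps = [fit.folds[fs.k].beta[j] - fs.S_full / fs.I_info for fs in scores]
    out.beta_tilde = float(np.mean(one_steps))
    half = norm.ppf(1.0 - alpha / 2.0) * sigma / (np.sqrt(n) * abs(out.I_info))
    out.ci = (out.beta_tilde - half, out.beta_tilde + half)
    return out


def pooled_test(
    fit: PEARLFit, j: int, lambda_tilde: float | None = None, alpha: float = 0.05
) -> CoordinateInference:
    """Pooled de-correlated score test of H0: beta_j = 0 (two-sided)."""
    return infer_coordinate(fit, j, lambda_tilde, alpha)


def one_step_ci(
    fit: PEARLFit, j: int, lambda_tilde: float | None = None, alpha: float = 0.05
) -> CoordinateInference:
    """Pooled one-step estimate of beta_j with a symmetric normal interval."""
    return infer_coordinate(fit, j, lambda_tilde, alpha)


def test_table(
    fit: PEARLFit,
    J: list[int] | np.ndarray,
    alpha: float = 0.05,
    fdr: bool = False,
    lambda_tilde: float | None = None,
) -> pd.DataFrame:
    """Per-coordinate inference table; optionally appends BH q-values.

    Columns: j, beta_hat, beta_tilde, se, z, p, ci_lo, ci_hi (and q with
    ``fdr=True``).  Degenerate coordinates carry NaN statistics.
    """
    J = list(J)
    if not J:
        raise ValueError("coordinate set J must be nonempty")
    rows = []
    for j in J:
        ci = infer_coordinate(fit, j, lambda_tilde, alpha)
        rows.append(
            dict(j=j, beta_hat=ci.beta_hat, beta_tilde=ci.beta_tilde, se=ci.se,
                 z=ci.z, p=ci.p_value, ci_lo=ci.ci[0], ci_hi=ci.ci[1],
                 degenerate=ci.degenerate)
        )
    table = pd.DataFrame(rows)
    if fdr:
        valid = table["p"].notna()
        q = np.full(len(table), np.nan)
        if valid.any():
            q[valid.to_numpy()] = multipletests(
                table.loc[valid, "p"].to_numpy(), method="fdr_bh"
            )[1]
        table["q"] = q
    return table
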