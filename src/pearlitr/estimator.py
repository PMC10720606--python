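"""Cross-fitted penalized estimation of the linear treatment rule.

For each fold k of a K-fold random partition: nuisances (propensity and
per-arm outcome means) are fitted on the fold's complement, doubly-robust
weights are formed on the fold's own rows with the estimated propensity
trimmed into [0.1, 0.9], and the fold coefficients solve the l1-penalized
weighted surrogate problem on those rows with a cross-validated penalty.  The
pooled coefficients are the plain average over folds, and the decision rule is
sgn(x'beta) with sgn(0) = +1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aipw import AIPWWeights, aipw_weights, trim_propensity
from .config import PearlConfig
from .nuisance import CrossFitPlan, NuisanceFit, fit_outcome, fit_propensity, make_folds
from .simulate import Dataset, sgn
from .solver import SolverResult, select_lambda, solve_penalized_surrogate

__all__ = ["FoldFit", "PEARLFit", "fit_pearl", "predict_rule"]


@dataclass
class FoldFit:
    """Everything produced for one fold: nuisances, weights, solved coefficients."""

    index: np.ndarray
    nuisance: NuisanceFit
    weights: AIPWWeights
    solver: SolverResult
    lam: float

    @property
    def beta(self) -> np.ndarray:
        return self.solver.beta


@dataclass
class PEARLFit:
    """A complete cross-fitted rule fit.

    ``beta`` is exactly the arithmetic mean of the per-fold coefficients.
    The covariate matrix is kept by reference so downstream inference can
    evaluate fold-level scores without re-reading data.
    """

    plan: CrossFitPlan
    folds: list[FoldFit]
    beta: np.ndarray
    X: np.ndarray
    config: PearlConfig


def _fit_fold_nuisances(
    X: np.ndarray, A: np.ndarray, Y: np.ndarray,
    train_idx: np.ndarray, config: PearlConfig, seed: int, k: int,
) -> NuisanceFit:
    nc = config.nuisance
    try:
        if nc.propensity_fn is not None:
            prop = nc.propensity_fn
        else:
            prop = fit_propensity(
                X[train_idx], A[train_idx], nc.propensity_method,
                screen_d=nc.screen_d, cv=nc.cv, seed=seed,
            )
        if nc.outcome_fns is not None:
            outc = nc.outcome_fns
        else:
            outc = fit_outcome(
                X[train_idx], A[train_idx], Y[train_idx], nc.outcome_method,
                screen_d=nc.screen_d, cv=nc.cv,
                min_per_arm=nc.min_per_arm, seed=seed,
            )
    except Exception as err:
        raise RuntimeError(f"nuisance fit failed for fold {k}: {err}") from err
    method = f"pi={nc.propensity_method},Q={nc.outcome_method}"
    if nc.propensity_fn is not None or nc.outcome_fns is not None:
        method += ",supplied"
    return NuisanceFit(propensity=prop, outcome=outc, method=method, train_index=train_idx)


def fold_weights(
    X: np.ndarray, A: np.ndarray, Y: np.ndarray,
    rows: np.ndarray, nuisance: NuisanceFit, trim: tuple[float, float],
) -> AIPWWeights:
    """Doubly-robust weights on ``rows`` using a complement-trained nuisance fit."""
    Xk = X[rows]
    pi1 = trim_propensity(nuisance.propensity(Xk), *trim)
    q1 = nuisance.outcome[0](Xk)
    qm1 = nuisance.outcome[1](Xk)
    return aipw_weights(Y[rows], A[rows], pi1, q1, qm1)


def fit_pearl(
    data: Dataset,
    config: PearlConfig | None = None,
    plan: CrossFitPlan | None = None,
) -> PEARLFit:
    """Fit the cross-fitted penalized rule estimator.

    A pre-built ``plan`` may be supplied (e.g. for paired-fold experiments);
    otherwise a uniformly random partition is drawn from the config seed.
    Columns are standardized to unit scale on each fold before solving, with
    coefficients mapped back, so the l1 penalty acts evenly across covariates.
    """
    config = config or PearlConfig()
    X, A, Y = data.X, data.A, data.Y
    n = data.n
    ss = np.random.SeedSequence(config.seed)
    seed_folds, seed_nuis, seed_cv = ss.spawn(3)
    if plan is None:
        plan = make_folds(n, config.K, seed_folds)
    elif plan.n != n:
        raise ValueError("supplied plan does not cover the dataset rows")

    nuis_seeds = [int(s.generate_state(1)[0] % 2**31) for s in seed_nuis.spawn(plan.K)]
    cv_seeds = [int(s.generate_state(1)[0] % 2**31) for s in seed_cv.spawn(plan.K)]

    folds: list[FoldFit] = []
    betas = []
    for k in range(plan.K):
        rows = plan.folds[k]
        train_idx = plan.complement(k)
        for arm in (1, -1):
            if not np.any(A[train_idx] == arm):
                raise ValueError(f"training complement of fold {k} lacks arm {arm:+d}")
        nuis = _fit_fold_nuisances(X, A, Y, train_idx, config, nuis_seeds[k], k)
        w = fold_weights(X, A, Y, rows, nuis, config.nuisance.trim)

        Xk = X[rows]
        scale = Xk.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        Xs = Xk / scale
        if config.lam.fixed is not None:
            lam = float(config.lam.fixed)
        else:
            lam = select_lambda(
                Xs, w.Omega_plus, w.Omega_minus,
                cv_folds=config.lam.cv_folds, seed=cv_seeds[k],
                grid_size=config.lam.grid_size, grid_eps=config.lam.grid_eps,
                options=config.cv_solver_options(config.lam),
            )
        sol = solve_penalized_surrogate(
            Xs, w.Omega_plus, w.Omega_minus, lam, options=config.solver
        )
        sol.beta = sol.beta / scale  # back to the raw covariate scale
        folds.append(FoldFit(index=rows, nuisance=nuis, weights=w, solver=sol, lam=lam))
        betas.append(sol.beta)

    beta = np.mean(betas, axis=0)
    return PEARLFit(plan=plan, folds=folds, beta=beta, X=X, config=config)


def predict_rule(fit: PEARLFit | np.ndarray, Xnew: np.ndarray) -> np.ndarray:
    """Decisions sgn(x'beta) in {-1, +1} with sgn(0) = +1."""
    beta = fit.beta if isinstance(fit, PEARLFit) else np.asarray(fit, dtype=float)
    Xnew = np.asarray(Xnew, dtype=float)
    if Xnew.shape[-1] != beta.shape[0]:
        raise ValueError(
            f"Xnew has {Xnew.shape[-1]} columns, fit has {beta.shape[0]} coefficients"
        )
    return sgn(Xnew @ beta)
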