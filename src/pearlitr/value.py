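"""Single-split inference for the value of the estimated rule.

The data are split into two halves: the rule and the nuisance models are
fitted on the first half only; on the second half, doubly-robust weights built
from the first-half nuisances give the value estimate

    V_hat = mean_{i in half 2}[ W_1,i 1{D(x_i)=1} + W_-1,i 1{D(x_i)=-1} ]

with the plug-in variance sigma_V^2 = mean[(W_{D(x)} - V_hat)^2] and the
normal interval V_hat +/- z_{1-alpha/2} sigma_V / sqrt(n2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .aipw import aipw_weights, trim_propensity
from .config import PearlConfig
from .estimator import PEARLFit, fit_pearl, predict_rule
from .nuisance import fit_outcome, fit_propensity
from .simulate import Dataset

__all__ = ["ValueInference", "split_value_inference"]


@dataclass
class ValueInference:
    """Value estimate with a normal confidence interval from a single split."""

    v_hat: float
    sigma_v: float
    ci: tuple[float, float]
    n1: int
    n2: int
    alpha: float
    beta: np.ndarray
    fit: PEARLFit | None = None


def split_value_inference(
    data: Dataset,
    config: PearlConfig | None = None,
    alpha: float = 0.05,
    seed: int | None = None,
) -> ValueInference:
    """Estimate the value of the fitted rule with a single-split normal CI.

    The split is a fresh random half (n1 = floor(n/2) training rows); the rule
    is fitted on the training half with its own internal cross-fitting, and
    the nuisances entering the held-out weights are refit on the full training
    half.  Both treatment arms must be present in both halves.
    """
    config = config or PearlConfig()
    if seed is None:
        seed = config.seed
    n = data.n
    if n < 4 * config.K:
        raise ValueError(f"need n >= 4K for a half-split with K={config.K} folds")
    ss = np.random.SeedSequence(seed)
    seed_split, seed_fit = ss.spawn(2)
    perm = np.random.default_rng(seed_split).permutation(n)
    n1 = n // 2
    idx1, idx2 = np.sort(perm[:n1]), np.sort(perm[n1:])
    for name, idx in (("training", idx1), ("inference", idx2)):
        for arm in (1, -1):
            if not np.any(data.A[idx] == arm):
                raise ValueError(f"{name} half lacks treatment arm {arm:+d}")

    train = Dataset(X=data.X[idx1], A=data.A[idx1], Y=data.Y[idx1],
                    column_names=list(data.column_names))
    fit_cfg = PearlConfig(
        K=config.K, seed=int(seed_fit.generate_state(1)[0] % 2**31),
        alpha=alpha, nuisance=config.nuisance, solver=config.solver,
        lam=config.lam, lam_tilde=config.lam_tilde,
    )
    fit = fit_pearl(train, fit_cfg)

    # nuisances for the held-out weights: refit on the whole training half
    nc = config.nuisance
    if nc.propensity_fn is not None:
        prop = nc.propensity_fn
    else:
        prop = fit_propensity(train.X, train.A, nc.propensity_method,
                              screen_d=nc.screen_d, cv=nc.cv, seed=fit_cfg.seed)
    if nc.outcome_fns is not None:
        outc = nc.outcome_fns
    else:
        outc = fit_outcome(train.X, train.A, train.Y, nc.outcome_method,
                           screen_d=nc.screen_d, cv=nc.cv,
                           min_per_arm=nc.min_per_arm, seed=fit_cfg.seed)

    X2, A2, Y2 = data.X[idx2], data.A[idx2], data.Y[idx2]
    pi1 = trim_propensity(prop(X2), *nc.trim)
    w = aipw_weights(Y2, A2, pi1, outc[0](X2), outc[1](X2))
    d = predict_rule(fit, X2)
    w_rule = np.where(d == 1, w.W1, w.Wm1)
    n2 = len(idx2)
    v_hat = float(w_rule.mean())
    sigma_v = float(np.sqrt(np.mean((w_rule - v_hat) ** 2)))
    half = norm.ppf(1.0 - alpha / 2.0) * sigma_v / np.sqrt(n2)
    return ValueInference(
        v_hat=v_hat, sigma_v=sigma_v, ci=(v_hat - half, v_hat + half),
        n1=n1, n2=n2, alpha=alpha, beta=fit.beta, fit=fit,
    )
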