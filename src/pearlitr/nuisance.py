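"""Cross-fitting folds and nuisance estimation for the propensity and outcome models.

Two estimation routes are provided for each nuisance:

* ``penalized_logistic`` / ``penalized_linear`` — l1-penalized GLM fits with the
  penalty chosen by internal cross-validation on the training split only
  (scikit-learn ``LogisticRegressionCV`` / ``LassoCV``);
* ``screened_kernel`` — model-free distance-correlation screening of the
  response on the covariates, followed by Nadaraya-Watson smoothing with a
  product Gaussian kernel on the standardized retained coordinates
  (rule-of-thumb bandwidth h = 1.06 * n^(-1/(4+d))).

Cross-fitting discipline: a nuisance fit used to weight fold k is trained on
the complement of fold k; the trained-on index set is recorded on the fit so
the discipline can be asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.linear_model import LassoCV, LogisticRegressionCV

__all__ = [
    "CrossFitPlan",
    "NuisanceFit",
    "make_folds",
    "fit_propensity",
    "fit_outcome",
    "screen_variables",
    "distance_correlation",
]

_PROB_EPS = 1e-9  # keep raw propensity predictions strictly inside (0, 1)


@dataclass(frozen=True)
class CrossFitPlan:
    """A random partition of row indices 0..n-1 into K nearly equal folds."""

    K: int
    folds: tuple[np.ndarray, ...]

    @property
    def n(self) -> int:
        return sum(len(f) for f in self.folds)

    def complement(self, k: int) -> np.ndarray:
        """All indices outside fold k (the nuisance training set for fold k)."""
        return np.concatenate([f for i, f in enumerate(self.folds) if i != k])


@dataclass
class NuisanceFit:
    """Fitted nuisance functions for one cross-fitting fold complement."""

    propensity: Callable[[np.ndarray], np.ndarray] | None
    outcome: tuple[Callable[[np.ndarray], np.ndarray], Callable[[np.ndarray], np.ndarray]] | None
    method: str = ""
    train_index: np.ndarray | None = None


def make_folds(n: int, K: int, seed: int | np.random.SeedSequence = 0) -> CrossFitPlan:
    """Uniformly random partition into K folds with sizes in {floor(n/K), floor(n/K)+1}."""
    if K < 2:
        raise ValueError("K must be at least 2")
    if n < 2 * K:
        raise ValueError(f"need n >= 2K rows (got n={n}, K={K})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return CrossFitPlan(K=K, folds=tuple(np.sort(f) for f in np.array_split(perm, K)))


# ---------------------------------------------------------------------------
# distance-correlation screening
# ---------------------------------------------------------------------------

def _dcenter(D: np.ndarray) -> np.ndarray:
    row = D.mean(axis=0, keepdims=True)
    col = D.mean(axis=1, keepdims=True)
    return D - row - col + D.mean()


def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Sample distance correlation (V-statistic) between two 1-d samples.

    Returns 0 when either sample is constant (zero distance variance).
    """
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    A = _dcenter(cdist(x, x, "cityblock"))
    B = _dcenter(cdist(y, y, "cityblock"))
    dcov2 = (A * B).mean()
    dvar_x = (A * A).mean()
    dvar_y = (B * B).mean()
    denom = np.sqrt(dvar_x * dvar_y)
    if denom <= 0.0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / denom))


def screen_variables(X: np.ndarray, response: np.ndarray, d: int) -> list[int]:
    """Indices of the d covariates with largest distance correlation with the response.

    Ties break toward the lower index.  When p <= d, all indices are returned
    in their original order (no screening needed).
    """
    if d < 1:
        raise ValueError("screening budget d must be >= 1")
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if p <= d:
        return list(range(p))
    y = np.asarray(response, dtype=float).reshape(-1, 1)
    B = _dcenter(cdist(y, y, "cityblock"))
    dvar_y = (B * B).mean()
    scores = np.empty(p)
    for j in range(p):
        xj = X[:, j].reshape(-1, 1)
        A = _dcenter(cdist(xj, xj, "cityblock"))
        dvar_x = (A * A).mean()
        denom = np.sqrt(dvar_x * dvar_y)
        scores[j] = 0.0 if denom <= 0 else np.sqrt(max((A * B).mean(), 0.0) / denom)
    order = np.argsort(-scores, kind="stable")  # stable sort -> lower index wins ties
    return [int(j) for j in order[:d]]


def default_screen_budget(n: int) -> int:
    """Sure-independence-screening convention: floor(n / log n)."""
    return max(1, int(n / np.log(n)))


# ---------------------------------------------------------------------------
# kernel smoother
# ---------------------------------------------------------------------------

class _KernelSmoother:
    """Nadaraya-Watson regression with a product Gaussian kernel.

    Operates on a retained subset of covariates, standardized by the training
    mean/sd; predictions with vanishing total kernel weight fall back to the
    training mean of the response.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, retained: Sequence[int]):
        self.retained = np.asarray(retained, dtype=int)
        Xr = np.asarray(X, dtype=float)[:, self.retained]
        self.mean_ = Xr.mean(axis=0)
        sd = Xr.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        self.Z_ = (Xr - self.mean_) / self.scale_
        self.y_ = np.asarray(y, dtype=float)
        n, d = self.Z_.shape
        self.h_ = 1.06 * n ** (-1.0 / (4.0 + d))
        self.fallback_ = float(self.y_.mean())

    def __call__(self, Xnew: np.ndarray) -> np.ndarray:
        Znew = (np.asarray(Xnew, dtype=float)[:, self.retained] - self.mean_) / self.scale_
        out = np.empty(Znew.shape[0])
        for start in range(0, Znew.shape[0], 2048):
            block = Znew[start : start + 2048]
            D2 = cdist(block, self.Z_, "sqeuclidean")
            W = np.exp(-D2 / (2.0 * self.h_**2))
            tot = W.sum(axis=1)
            num = W @ self.y_
            blockout = np.where(tot > 0, num / np.where(tot > 0, tot, 1.0), self.fallback_)
            out[start : start + block.shape[0]] = blockout
        return out


# ---------------------------------------------------------------------------
# nuisance fits
# ---------------------------------------------------------------------------

def _check_both_arms(A: np.ndarray) -> None:
    if not (np.any(A == 1) and np.any(A == -1)):
        raise ValueError("training data must contain both treatment arms")


def fit_propensity(
    X: np.ndarray,
    A: np.ndarray,
    method: str = "screened_kernel",
    *,
    screen_d: int | None = None,
    cv: int = 3,
    seed: int = 0,
) -> Callable[[np.ndarray], np.ndarray]:
    """Fit x -> P(A=1 | x) and return a prediction function with outputs in (0, 1).

    ``penalized_logistic`` uses l1-penalized logistic regression with the
    penalty level chosen by cross-validation; ``screened_kernel`` screens A on
    the covariates by distance correlation and kernel-smooths the indicator
    1{A=1} on the retained coordinates.  Trimming to [0.1, 0.9] is the
    caller's job (it applies to estimated propensities only).
    """
    X = np.asarray(X, dtype=float)
    A = np.asarray(A)
    _check_both_arms(A)
    if method == "penalized_logistic":
        model = LogisticRegressionCV(
            l1_ratios=(1.0,),
            solver="liblinear",
            Cs=np.logspace(-2.5, 2.5, 8),
            cv=cv,
            scoring="neg_log_loss",
            max_iter=3000,
            random_state=seed,
            use_legacy_attributes=False,
        )
        model.fit(X, (A == 1).astype(int))

        def predict(Xnew: np.ndarray) -> np.ndarray:
            pr = model.predict_proba(np.asarray(Xnew, dtype=float))[:, 1]
            return np.clip(pr, _PROB_EPS, 1.0 - _PROB_EPS)

        predict.coef_ = model.coef_.ravel()  # expose for diagnostics
        return predict
    if method == "screened_kernel":
        d = screen_d if screen_d is not None else default_screen_budget(len(A))
        retained = screen_variables(X, (A == 1).astype(float), d)
        smoother = _KernelSmoother(X, (A == 1).astype(float), retained)

        def predict(Xnew: np.ndarray) -> np.ndarray:
            return np.clip(smoother(Xnew), _PROB_EPS, 1.0 - _PROB_EPS)

        return predict
    raise ValueError(f"unknown propensity method {method!r}")


def _fit_arm_regression(
    X: np.ndarray, y: np.ndarray, method: str, screen_d: int | None, cv: int, seed: int
) -> Callable[[np.ndarray], np.ndarray]:
    if np.std(y) == 0.0:  # constant target: intercept-only solution
        c = float(y[0]) if len(y) else 0.0
        return lambda Xnew: np.full(np.asarray(Xnew).shape[0], c)
    if method == "penalized_linear":
        model = LassoCV(cv=cv, alphas=30, random_state=seed, max_iter=5000)
        model.fit(X, y)
        return lambda Xnew: model.predict(np.asarray(Xnew, dtype=float))
    if method == "screened_kernel":
        d = screen_d if screen_d is not None else default_screen_budget(len(y))
        retained = screen_variables(X, y, d)
        return _KernelSmoother(X, y, retained)
    raise ValueError(f"unknown outcome method {method!r}")


def fit_outcome(
    X: np.ndarray,
    A: np.ndarray,
    Y: np.ndarray,
    method: str = "screened_kernel",
    *,
    screen_d: int | None = None,
    cv: int = 3,
    min_per_arm: int = 10,
    seed: int = 0,
) -> tuple[Callable[[np.ndarray], np.ndarray], Callable[[np.ndarray], np.ndarray]]:
    """Fit per-arm outcome regressions (x -> Q(1;x), x -> Q(-1;x)).

    Each arm is fitted on its own rows only, so misspecification in one arm
    does not contaminate the other.
    """
    X = np.asarray(X, dtype=float)
    A = np.asarray(A)
    Y = np.asarray(Y, dtype=float)
    _check_both_arms(A)
    fits = {}
    for a in (1, -1):
        rows = np.flatnonzero(A == a)
        if len(rows) < min_per_arm:
            raise ValueError(
                f"arm {a:+d} has only {len(rows)} rows (< min_per_arm={min_per_arm})"
            )
        fits[a] = _fit_arm_regression(X[rows], Y[rows], method, screen_d, cv, seed)
    return fits[1], fits[-1]
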