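"""Logistic surrogate loss and the two l1-penalized solvers at the heart of the method.

The estimation problem replaces the 0-1 value objective with a strictly convex
surrogate: each observation carries a nonnegative weight ``Omega_plus``
encouraging decision +1 and ``Omega_minus`` encouraging decision -1, and the
rule coefficients solve

    min_beta  mean_i[ Omega+_i phi(x_i'beta) + Omega-_i phi(-x_i'beta) ]  + lambda ||beta||_1

with the logistic surrogate phi(t) = log(1 + exp(-t)).  This is a case-weighted
binary surrogate classification: row i contributes pseudo-label +1 with weight
Omega+_i and pseudo-label -1 with weight Omega-_i.  The solver is FISTA
(accelerated proximal gradient) with a spectral step size and adaptive restart;
convergence is certified by the subgradient KKT residual.

The de-correlation regression projects covariate j on the remaining covariates
under the per-row curvature weights h_i = (second derivative of the surrogate
loss at the fitted coefficients):

    min_w  mean_i[ h_i (x_ij - x_i,-j'w)^2 ]  + lambda_tilde ||w||_1

solved by cyclic coordinate descent on the weighted Gram matrix.

Penalty levels are chosen by cross-validation over a log-spaced grid anchored
at the data-driven lambda_max (the smallest penalty that zeroes the solution),
which adapts the glmnet convention to the weighted surrogate; ties in the CV
loss break toward the smallest lambda (less bias entering the one-step
correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "SolverOptions",
    "SolverResult",
    "surrogate_derivatives",
    "surrogate_objective",
    "solve_penalized_surrogate",
    "solve_decorrelation_lasso",
    "select_lambda",
    "select_lambda_tilde",
]


# ---------------------------------------------------------------------------
# logistic surrogate
# ---------------------------------------------------------------------------

def phi(t: np.ndarray) -> np.ndarray:
    """Logistic surrogate phi(t) = log(1 + exp(-t)), overflow-safe."""
    return np.logaddexp(0.0, -np.asarray(t, dtype=float))


def phi_prime(t: np.ndarray) -> np.ndarray:
    """phi'(t) = -1 / (1 + exp(t)); bounded in (-1, 0) with phi'(0) = -1/2."""
    return -expit(-np.asarray(t, dtype=float))


def phi_double_prime(t: np.ndarray) -> np.ndarray:
    """phi''(t) = exp(t) / (1 + exp(t))^2; positive, at most 1/4, even in t."""
    t = np.asarray(t, dtype=float)
    s = expit(t)
    return s * (1.0 - s)


def surrogate_derivatives(t: np.ndarray | float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(phi, phi', phi'') of the logistic surrogate at t."""
    return phi(t), phi_prime(t), phi_double_prime(t)


def loss_gradient_scalars(
    z: np.ndarray, omega_plus: np.ndarray, omega_minus: np.ndarray
) -> np.ndarray:
    """Per-row first-derivative factor of the weighted surrogate loss at margins z.

    The gradient of the loss w.r.t. beta is mean_i[ s_i x_i ] with
    s_i = Omega+_i phi'(z_i) - Omega-_i phi'(-z_i).
    """
    return omega_plus * phi_prime(z) - omega_minus * phi_prime(-z)


def loss_hessian_scalars(
    z: np.ndarray, omega_plus: np.ndarray, omega_minus: np.ndarray
) -> np.ndarray:
    """Per-row curvature factor h_i = Omega+_i phi''(z_i) + Omega-_i phi''(-z_i)."""
    # phi'' is even, so this equals (Omega+ + Omega-) * phi''(z); kept general.
    return omega_plus * phi_double_prime(z) + omega_minus * phi_double_prime(-z)


def surrogate_objective(
    beta: np.ndarray,
    X: np.ndarray,
    omega_plus: np.ndarray,
    omega_minus: np.ndarray,
    lam: float = 0.0,
) -> float:
    """Penalized weighted surrogate objective at beta."""
    z = X @ beta
    smooth = float(np.mean(omega_plus * phi(z) + omega_minus * phi(-z)))
    return smooth + lam * float(np.sum(np.abs(beta)))


# ---------------------------------------------------------------------------
# solver plumbing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolverOptions:
    """Numerical controls shared by both penalized solvers.

    tol: relative-objective convergence tolerance; max_iter: iteration cap;
    kkt_tol: subgradient KKT residual tolerance, relative to the gradient
    scale of the problem.
    """

    tol: float = 1e-8
    max_iter: int = 10_000
    kkt_tol: float = 1e-6


@dataclass
class SolverResult:
    beta: np.ndarray
    objective: float
    lam: float
    iterations: int
    converged: bool
    kkt_residual: float = np.nan


def _soft(v: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - thr, 0.0)


def _kkt_residual(grad: np.ndarray, beta: np.ndarray, lam: float) -> float:
    """Max violation of the l1 subgradient optimality conditions."""
    active = beta != 0.0
    res_active = np.abs(grad[active] + lam * np.sign(beta[active]))
    res_zero = np.maximum(np.abs(grad[~active]) - lam, 0.0)
    pieces = [res_active, res_zero]
    return float(max((arr.max() for arr in pieces if arr.size), default=0.0))


def _spectral_bound(X: np.ndarray, row_weights: np.ndarray, iters: int = 30) -> float:
    """Largest eigenvalue of X' diag(row_weights) X / n via power iteration."""
    n, p = X.shape
    rng = np.random.default_rng(0)
    v = rng.standard_normal(p)
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(iters):
        u = (X @ v) * row_weights
        w = X.T @ u / n
        lam = float(np.linalg.norm(w))
        if lam == 0.0:
            return 0.0
        v = w / lam
    return lam


def solve_penalized_surrogate(
    X: np.ndarray,
    omega_plus: np.ndarray,
    omega_minus: np.ndarray,
    lam: float,
    options: SolverOptions = SolverOptions(),
    beta0: np.ndarray | None = None,
) -> SolverResult:
    """Minimize the l1-penalized weighted logistic-surrogate loss by FISTA.

    The step size is 1/L with L a power-iteration bound on the loss curvature
    (phi'' <= 1/4); monotonicity is enforced by adaptive restart.  Failure to
    reach the KKT tolerance within ``options.max_iter`` is flagged via
    ``converged=False``, never raised silently.

    With all weights identically zero the loss is constant and the exact
    minimizer beta = 0 is returned immediately (degenerate zero-signal data).
    """
    X = np.asarray(X, dtype=float)
    op = np.asarray(omega_plus, dtype=float)
    om = np.asarray(omega_minus, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if not (np.all(np.isfinite(op)) and np.all(np.isfinite(om))):
        raise ValueError("weights must be finite")
    if np.any(op < 0) or np.any(om < 0):
        raise ValueError("Omega weights must be nonnegative")
    n, p = X.shape

    total = op + om
    if not np.any(total > 0):
        return SolverResult(
            beta=np.zeros(p), objective=0.0, lam=lam, iterations=0,
            converged=True, kkt_residual=0.0,
        )

    L = max(_spectral_bound(X, total / 4.0), 1e-12) * 1.05
    step = 1.0 / L

    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    y = beta.copy()
    t_acc = 1.0

    def grad(b: np.ndarray) -> np.ndarray:
        return X.T @ loss_gradient_scalars(X @ b, op, om) / n

    obj = surrogate_objective(beta, X, op, om, lam)
    grad_scale = max(1.0, float(np.max(np.abs(grad(np.zeros(p))))))
    kkt_thresh = options.kkt_tol * grad_scale
    res = np.inf
    it = 0
    for it in range(1, options.max_iter + 1):
        beta_new = _soft(y - step * grad(y), step * lam)
        obj_new = surrogate_objective(beta_new, X, op, om, lam)
        if obj_new > obj:  # adaptive restart: drop momentum
            t_acc = 1.0
            y = beta.copy()
            beta_new = _soft(y - step * grad(y), step * lam)
            obj_new = surrogate_objective(beta_new, X, op, om, lam)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_acc**2))
        y = beta_new + ((t_acc - 1.0) / t_next) * (beta_new - beta)
        beta, t_acc = beta_new, t_next
        stalled = abs(obj - obj_new) <= options.tol * max(1.0, abs(obj_new))
        obj = obj_new
        # certify optimality only once progress slows (KKT check costs a pass)
        if stalled or it % 25 == 0:
            res = _kkt_residual(grad(beta), beta, lam)
            if res <= kkt_thresh:
                break

    if not np.isfinite(res):
        res = _kkt_residual(grad(beta), beta, lam)
    converged = res <= kkt_thresh
    return SolverResult(
        beta=beta, objective=surrogate_objective(beta, X, op, om, lam),
        lam=lam, iterations=it, converged=converged, kkt_residual=res,
    )


# ---------------------------------------------------------------------------
# weighted lasso (de-correlation regression)
# ---------------------------------------------------------------------------

def _weighted_lasso(
    Z: np.ndarray,
    y: np.ndarray,
    h: np.ndarray,
    lam: float,
    options: SolverOptions,
    w0: np.ndarray | None = None,
    gram: tuple[np.ndarray, np.ndarray] | None = None,
) -> SolverResult:
    """min_w mean_i[h_i (y_i - Z_i'w)^2] + lam ||w||_1 by cyclic coordinate descent."""
    n, q = Z.shape
    if gram is None:
        Zh = Z * h[:, None]
        G = Z.T @ Zh          # q x q weighted Gram
        b = Zh.T @ y          # q
    else:
        G, b = gram
    diag = np.diag(G).copy()
    w = np.zeros(q) if w0 is None else np.asarray(w0, dtype=float).copy()
    thr = n * lam / 2.0
    Gw = G @ w

    def sweep(indices) -> float:
        max_delta = 0.0
        for l in indices:
            dl = diag[l]
            if dl <= 0.0:
                continue
            rho = b[l] - Gw[l] + dl * w[l]
            mag = abs(rho) - thr
            new = 0.0 if mag <= 0.0 else (mag if rho > 0.0 else -mag) / dl
            delta = new - w[l]
            if delta != 0.0:
                Gw[:] += G[:, l] * delta
                w[l] = new
                if abs(delta) > max_delta:
                    max_delta = abs(delta)
        return max_delta

    it = 0
    while it < options.max_iter:
        it += 1
        md = sweep(range(q))  # full pass (checks the inactive set)
        if md <= options.tol * max(1.0, float(np.max(np.abs(w), initial=0.0))):
            break
        # iterate the active set to convergence before the next full pass
        while it < options.max_iter:
            active = np.flatnonzero(w)
            if active.size == 0:
                break
            it += 1
            md = sweep(active)
            if md <= options.tol * max(1.0, float(np.max(np.abs(w)))):
                break
    grad = 2.0 * (G @ w - b) / n
    res = _kkt_residual(grad, w, lam)
    grad_scale = max(1.0, float(np.max(np.abs(2.0 * b / n))))
    obj = float(np.mean(h * (y - Z @ w) ** 2)) + lam * float(np.sum(np.abs(w)))
    return SolverResult(
        beta=w, objective=obj, lam=lam, iterations=it,
        converged=res <= options.kkt_tol * grad_scale * 10, kkt_residual=res,
    )


def solve_decorrelation_lasso(
    X: np.ndarray,
    j: int,
    hessian_weights: np.ndarray,
    lambda_tilde: float,
    options: SolverOptions = SolverOptions(),
    w0: np.ndarray | None = None,
) -> SolverResult:
    """Weighted-lasso projection of covariate j on the remaining covariates.

    ``hessian_weights`` are the per-row curvature factors of the surrogate
    loss evaluated at the fitted fold coefficients.
    """
    X = np.asarray(X, dtype=float)
    h = np.asarray(hessian_weights, dtype=float)
    if lambda_tilde < 0:
        raise ValueError("lambda_tilde must be nonnegative")
    if np.any(h < 0) or not np.all(np.isfinite(h)):
        raise ValueError("hessian weights must be finite and nonnegative")
    if not np.any(h > 0):
        raise ValueError("all-zero curvature weights: de-correlation is undefined")
    Z = np.delete(X, j, axis=1)
    y = X[:, j]
    return _weighted_lasso(Z, y, h, lambda_tilde, options, w0=w0)


# ---------------------------------------------------------------------------
# penalty selection by cross-validation
# ---------------------------------------------------------------------------

def _cv_split(n: int, folds: int, seed) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    return [np.sort(f) for f in np.array_split(rng.permutation(n), folds)]


def make_lambda_grid(lam_max: float, size: int, eps: float = 0.01) -> np.ndarray:
    """Log-spaced grid from lam_max down to eps * lam_max (descending)."""
    lam_max = max(lam_max, 1e-12)
    return lam_max * np.logspace(0.0, np.log10(eps), size)


def select_lambda(
    X: np.ndarray,
    omega_plus: np.ndarray,
    omega_minus: np.ndarray,
    grid: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    grid_size: int = 50,
    grid_eps: float = 0.01,
    options: SolverOptions = SolverOptions(tol=1e-7, max_iter=2000),
) -> float:
    """Penalty level for the surrogate solver minimizing cross-validated loss.

    The returned value is always a grid member; CV ties break to the smallest
    lambda.  A single-element grid is returned untouched (no CV run).
    """
    X = np.asarray(X, dtype=float)
    op = np.asarray(omega_plus, dtype=float)
    om = np.asarray(omega_minus, dtype=float)
    n = X.shape[0]
    if grid is None:
        g0 = X.T @ loss_gradient_scalars(np.zeros(n), op, om) / n
        grid = make_lambda_grid(float(np.max(np.abs(g0))), grid_size, grid_eps)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid must be nonempty")
    if grid.size == 1:
        return float(grid[0])
    order = np.argsort(-grid)  # descend for warm starts
    losses = np.zeros(grid.size)
    for val_idx in _cv_split(n, cv_folds, seed):
        mask = np.ones(n, dtype=bool)
        mask[val_idx] = False
        Xtr, Xva = X[mask], X[val_idx]
        optr, omtr = op[mask], om[mask]
        opva, omva = op[val_idx], om[val_idx]
        beta_warm = None
        for gi in order:
            fit = solve_penalized_surrogate(Xtr, optr, omtr, float(grid[gi]),
                                            options=options, beta0=beta_warm)
            beta_warm = fit.beta
            losses[gi] += surrogate_objective(fit.beta, Xva, opva, omva, 0.0)
    best = losses.min()
    candidates = grid[losses <= best]
    return float(candidates.min())


def select_lambda_tilde(
    X: np.ndarray,
    j: int,
    hessian_weights: np.ndarray,
    grid: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    grid_size: int = 50,
    grid_eps: float = 0.01,
    options: SolverOptions = SolverOptions(tol=1e-7, max_iter=2000),
) -> float:
    """Penalty level for the de-correlation lasso by weighted-CV prediction loss."""
    X = np.asarray(X, dtype=float)
    h = np.asarray(hessian_weights, dtype=float)
    n = X.shape[0]
    Z_all = np.delete(X, j, axis=1)
    y_all = X[:, j]
    if grid is None:
        lam_max = float(np.max(np.abs(2.0 * (Z_all * h[:, None]).T @ y_all / n)))
        grid = make_lambda_grid(lam_max, grid_size, grid_eps)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid must be nonempty")
    if grid.size == 1:
        return float(grid[0])
    order = np.argsort(-grid)
    losses = np.zeros(grid.size)
    for val_idx in _cv_split(n, cv_folds, seed):
        mask = np.ones(n, dtype=bool)
        mask[val_idx] = False
        Ztr, yva_Z = Z_all[mask], Z_all[val_idx]
        ytr, yva = y_all[mask], y_all[val_idx]
        htr, hva = h[mask], h[val_idx]
        if not np.any(htr > 0) or not np.any(hva > 0):
            continue
        w_warm = None
        Zh = Ztr * htr[:, None]
        gram = (Ztr.T @ Zh, Zh.T @ ytr)
        for gi in order:
            fit = _weighted_lasso(Ztr, ytr, htr, float(grid[gi]), options,
                                  w0=w_warm, gram=gram)
            w_warm = fit.beta
            losses[gi] += float(np.mean(hva * (yva - yva_Z @ fit.beta) ** 2))
    best = losses.min()
    candidates = grid[losses <= best]
    return float(candidates.min())
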