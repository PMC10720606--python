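"""Doubly-robust AIPW weights and their positive/negative decomposition.

The per-observation weight encouraging treatment ``a`` is

    W_a = Y 1{A=a} / pi(a;X)  -  [1{A=a} - pi(a;X)] Q(a;X) / pi(a;X),

consistent for E[Q(a;X)] when either the propensity pi or the outcome model Q
is correct.  The value of a rule D is estimated by
``mean(W_1 1{D=1} + W_-1 1{D=-1})``.  For surrogate-loss optimization the pair
(W_1, W_-1) is folded into two nonnegative per-row weights:

    Omega_plus  = (W_1)_+ + (W_-1)_-     (evidence encouraging A = +1)
    Omega_minus = (W_1)_- + (W_-1)_+     (evidence encouraging A = -1)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AIPWWeights", "compute_weights", "decompose_weights", "trim_propensity"]


@dataclass
class AIPWWeights:
    """Per-observation doubly-robust weights and their decomposition."""

    W1: np.ndarray
    Wm1: np.ndarray
    Omega_plus: np.ndarray
    Omega_minus: np.ndarray


def compute_weights(
    Y: np.ndarray,
    A: np.ndarray,
    pi1_hat: np.ndarray,
    q1_hat: np.ndarray,
    qm1_hat: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-observation AIPW weights (W_1, W_-1).

    ``pi1_hat`` must lie strictly inside (0, 1); callers are expected to trim
    estimated propensities first (`trim_propensity`).  ``q1_hat``/``qm1_hat``
    are the outcome-model predictions Q(1;x) and Q(-1;x) on the same rows.
    """
    Y = np.asarray(Y, dtype=float)
    A = np.asarray(A)
    pi1_hat = np.asarray(pi1_hat, dtype=float)
    if np.any(pi1_hat <= 0.0) or np.any(pi1_hat >= 1.0):
        raise ValueError("propensities must lie strictly inside (0, 1); trim first")

    def _w(a: int, pia: np.ndarray, qa: np.ndarray) -> np.ndarray:
        ind = (A == a).astype(float)
        return (Y * ind - (ind - pia) * np.asarray(qa, dtype=float)) / pia

    return _w(1, pi1_hat, q1_hat), _w(-1, 1.0 - pi1_hat, qm1_hat)


def decompose_weights(W1: np.ndarray, Wm1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nonnegative decomposition (Omega_plus, Omega_minus) of (W_1, W_-1)."""
    W1 = np.asarray(W1, dtype=float)
    Wm1 = np.asarray(Wm1, dtype=float)
    if not (np.all(np.isfinite(W1)) and np.all(np.isfinite(Wm1))):
        raise ValueError("weights must be finite")
    omega_plus = np.maximum(W1, 0.0) + np.maximum(-Wm1, 0.0)
    omega_minus = np.maximum(-W1, 0.0) + np.maximum(Wm1, 0.0)
    return omega_plus, omega_minus


def aipw_weights(
    Y: np.ndarray,
    A: np.ndarray,
    pi1_hat: np.ndarray,
    q1_hat: np.ndarray,
    qm1_hat: np.ndarray,
) -> AIPWWeights:
    """Convenience wrapper: weights plus decomposition in one object."""
    W1, Wm1 = compute_weights(Y, A, pi1_hat, q1_hat, qm1_hat)
    op, om = decompose_weights(W1, Wm1)
    return AIPWWeights(W1=W1, Wm1=Wm1, Omega_plus=op, Omega_minus=om)


def trim_propensity(
    pi1_hat: np.ndarray, lo: float = 0.1, hi: float = 0.9
) -> np.ndarray:
    """Clamp estimated propensities into [lo, hi] (defaults 0.1, 0.9).

    Applied to estimated propensities only, never to a simulated truth;
    idempotent.
    """
    if not 0.0 < lo < hi < 1.0:
        raise ValueError(f"need 0 < lo < hi < 1, got lo={lo}, hi={hi}")
    return np.clip(np.asarray(pi1_hat, dtype=float), lo, hi)


def value_estimate(weights: AIPWWeights, decisions: np.ndarray) -> float:
    """AIPW value estimate mean(W_1 1{D=1} + W_-1 1{D=-1}) for decisions in {-1,+1}."""
    d = np.asarray(decisions)
    return float(np.mean(np.where(d == 1, weights.W1, weights.Wm1)))
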