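"""Dual quadratic-program solver for soft-margin kernel SVMs.

Both the base classifier and the transfer-learning adaptation lead to duals
of the same shape,

    min_a  1/2 a' Q a - p' a
    s.t.   y' a = 0,   0 <= a_i <= U_i,

with ``Q_ij = y_i y_j K(x_i, x_j)``.  The base SVM has ``p = 1`` and
``U = C``; the adapted SVM has ``p_k = 1 - y_k f_base(x_k)`` (the base
decision value without bias) and ``U_k = D c_k``.  The solver is a
sequential-minimal-optimisation loop with second-order working-set
selection, i.e. the maximal-violating-pair rule refined by the largest
decrease of the dual objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SmoResult", "solve_svm_dual", "QPError"]


class QPError(RuntimeError):
    """Raised when the dual solve fails to reach the KKT tolerance."""


@dataclass
class SmoResult:
    alpha: np.ndarray       # dual coefficients, in [0, U]
    bias: float             # b recovered from the KKT conditions
    n_iter: int
    kkt_gap: float          # final max-violating-pair gap

    @property
    def converged(self) -> bool:
        return np.isfinite(self.kkt_gap)


def solve_svm_dual(
    K: np.ndarray,
    y: np.ndarray,
    p: np.ndarray,
    upper: np.ndarray,
    tol: float = 1e-8,
    max_iter: int | None = None,
) -> SmoResult:
    """Solve the SVM dual QP by SMO.

    Parameters
    ----------
    K : (n, n) symmetric PSD kernel matrix.
    y : (n,) labels in {-1, +1}.
    p : (n,) linear term of the dual objective.
    upper : (n,) per-coefficient box bounds ``U_i > 0``.
    tol : stopping tolerance on the maximal-violating-pair gap; the KKT
        conditions of the returned solution hold within this tolerance.
    max_iter : cap on two-variable updates (default ``max(2000, 400 n)``).
    """
    y = np.asarray(y, dtype=float)
    p = np.broadcast_to(np.asarray(p, dtype=float), y.shape).copy()
    upper = np.broadcast_to(np.asarray(upper, dtype=float), y.shape).copy()
    n = y.size
    if K.shape != (n, n):
        raise ValueError(f"kernel matrix shape {K.shape} does not match {n} labels")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError("labels must be -1 or +1")
    if np.any(upper <= 0):
        raise ValueError("box bounds must be positive")
    if max_iter is None:
        max_iter = max(2000, 400 * n)

    Q = K * np.outer(y, y)
    alpha = np.zeros(n)
    grad = -p.copy()          # grad_i = (Q a)_i - p_i
    diagK = np.diag(K).copy()

    it = 0
    gap = np.inf
    while it < max_iter:
        # I_up / I_low of the maximal-violating-pair rule
        up = ((y > 0) & (alpha < upper)) | ((y < 0) & (alpha > 0))
        low = ((y > 0) & (alpha > 0)) | ((y < 0) & (alpha < upper))
        score = -y * grad
        if not up.any() or not low.any():
            gap = 0.0
            break
        m = np.max(score[up])
        M = np.min(score[low])
        gap = m - M
        if gap < tol:
            break
        i = np.flatnonzero(up)[np.argmax(score[up])]

        # second-order choice of j among violating candidates
        cand = low & (score < m)
        if not cand.any():
            break
        idx = np.flatnonzero(cand)
        b_j = m - score[idx]                      # > 0
        d = diagK[i] + diagK[idx] - 2.0 * K[i, idx]
        d = np.where(d <= 0, 1e-12, d)
        j = idx[np.argmax(b_j * b_j / d)]

        # analytic two-variable step: a_i += y_i t, a_j -= y_j t
        dij = diagK[i] + diagK[j] - 2.0 * K[i, j]
        if dij <= 0:
            dij = 1e-12
        t = (m - score[j]) / dij
        if y[i] > 0:
            t = min(t, upper[i] - alpha[i])
        else:
            t = min(t, alpha[i])
        if y[j] > 0:
            t = min(t, alpha[j])
        else:
            t = min(t, upper[j] - alpha[j])
        if t <= 0:
            break
        alpha[i] += y[i] * t
        alpha[j] -= y[j] * t
        grad += Q[:, i] * (y[i] * t) - Q[:, j] * (y[j] * t)
        it += 1
    else:
        raise QPError(
            f"SMO did not converge within {max_iter} iterations (gap={gap:.3e})"
        )

    bias = _recover_bias(alpha, y, grad, upper)
    return SmoResult(alpha=alpha, bias=bias, n_iter=it, kkt_gap=float(gap))


def _recover_bias(alpha: np.ndarray, y: np.ndarray, grad: np.ndarray,
                  upper: np.ndarray) -> float:
    """Bias from free support vectors, else the midpoint rule.

    At the optimum ``-y_i grad_i = y_i - f_nobias(x_i)`` holds, so every
    free coefficient (0 < a_i < U_i) pins the bias exactly; without free
    coefficients the bias lies between the I_up maximum and I_low minimum
    and the midpoint is taken.
    """
    score = -y * grad
    free = (alpha > 1e-8 * upper) & (alpha < upper * (1 - 1e-8))
    if free.any():
        return float(np.mean(score[free]))
    up = ((y > 0) & (alpha < upper)) | ((y < 0) & (alpha > 0))
    low = ((y > 0) & (alpha > 0)) | ((y < 0) & (alpha < upper))
    hi = np.max(score[up]) if up.any() else -np.inf
    lo = np.min(score[low]) if low.any() else np.inf
    if not np.isfinite(hi) and not np.isfinite(lo):
        return 0.0
    if not np.isfinite(hi):
        return float(lo)
    if not np.isfinite(lo):
        return float(hi)
    return float(0.5 * (hi + lo))
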