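"""Earth mover's distance between equal-size point sets.

The ground metric is squared Euclidean distance and the reported value is
the mean matching cost over points. The exact solver (Hungarian algorithm)
is used up to ``EXACT_LIMIT`` points; above that an entropic (Sinkhorn)
approximation with a small regularization is used.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["emd", "emd_match", "EXACT_LIMIT"]

EXACT_LIMIT = 512

#: entropic regularization, as a fraction of the median pairwise cost
SINKHORN_EPS_FRACTION = 0.01
SINKHORN_MAX_ITER = 2000
SINKHORN_TOL = 1e-9


def _cost_matrix(a, b):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(
            f"point sets must have equal shape, got {a.shape} vs {b.shape}"
        )
    diff = a[:, None, :] - b[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def emd_match(a, b) -> np.ndarray:
    """Optimal bijection as an index array sigma with a[i] matched to
    b[sigma[i]] (exact Hungarian solver)."""
    cost = _cost_matrix(a, b)
    rows, cols = linear_sum_assignment(cost)
    sigma = np.empty(len(a), dtype=int)
    sigma[rows] = cols
    return sigma


def emd(a, b, exact: bool | None = None) -> float:
    """Mean minimum-cost matching between two equal-size point sets."""
    cost = _cost_matrix(a, b)
    n = len(cost)
    if exact is None:
        exact = n <= EXACT_LIMIT
    if exact:
        rows, cols = linear_sum_assignment(cost)
        return float(cost[rows, cols].mean())
    return _sinkhorn_cost(cost)


def _sinkhorn_cost(cost) -> float:
    """Entropic OT cost with uniform marginals (log-domain Sinkhorn).

    P_ij = exp((f_i + g_j - C_ij) / eps) is alternately projected onto the
    two uniform-marginal constraints; the returned value is <P, C> * n,
    i.e. the mean per-point matching cost under the entropic plan.
    """
    n = len(cost)
    scale = np.median(cost)
    if scale == 0:
        return 0.0
    eps = SINKHORN_EPS_FRACTION * scale
    f = np.zeros(n)
    g = np.zeros(n)
    log_mu = -np.log(n)
    for _ in range(SINKHORN_MAX_ITER):
        f_new = eps * log_mu - eps * _logsumexp(
            (g[None, :] - cost) / eps, axis=1
        )
        g_new = eps * log_mu - eps * _logsumexp(
            (f_new[:, None] - cost) / eps, axis=0
        )
        delta = np.abs(f_new - f).max()
        f, g = f_new, g_new
        if delta < SINKHORN_TOL:
            break
    logP = (f[:, None] + g[None, :] - cost) / eps
    P = np.exp(logP)
    P /= P.sum()
    return float((P * cost).sum())


def _logsumexp(x, axis):
    m = x.max(axis=axis, keepdims=True)
    return (m + np.log(np.exp(x - m).sum(axis=axis, keepdims=True))).squeeze(
        axis
    )
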