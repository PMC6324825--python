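"""Didactic block coordinate-descent graphical-lasso solver.

A slow, transparent pure-numpy implementation of the classic
block-coordinate-descent algorithm for the L1-penalised precision
estimation problem

    minimise  -log det(T) + trace(S T) + rho * ||offdiag(T)||_1 .

One column/row of the working covariance W is updated at a time by
solving a lasso subproblem with plain cyclic coordinate descent. Intended
for verification on small instances (p <= ~60), not production use — the
production path solves the same problem through scikit-learn.
"""

from __future__ import annotations

import numpy as np


def _lasso_cd(
    Q: np.ndarray, b: np.ndarray, rho: float, tol: float, max_iter: int
) -> np.ndarray:
    """Cyclic coordinate descent for 0.5 x'Qx - b'x + rho ||x||_1."""
    p = b.size
    x = np.zeros(p)
    diag = np.diag(Q)
    for _ in range(max_iter):
        x_max = 0.0
        d_max = 0.0
        for j in range(p):
            old = x[j]
            r = b[j] - Q[j] @ x + diag[j] * old
            new = np.sign(r) * max(abs(r) - rho, 0.0) / diag[j]
            x[j] = new
            d_max = max(d_max, abs(new - old))
            x_max = max(x_max, abs(new))
        if d_max <= tol * max(x_max, 1e-12):
            break
    return x


def glasso_reference(
    S: np.ndarray,
    rho: float,
    tol: float = 1e-7,
    max_iter: int = 200,
    inner_tol: float = 1e-9,
    inner_max_iter: int = 2000,
) -> np.ndarray:
    """Solve the graphical lasso by block coordinate descent; returns Theta."""
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    # off-diagonal penalty only: the working covariance keeps the empirical
    # diagonal (the diagonal of Theta is unpenalised)
    W = S.copy()
    betas = np.zeros((p, p))  # column j's lasso coefficients (row j unused)
    mask = ~np.eye(p, dtype=bool)
    for _ in range(max_iter):
        W_old = W.copy()
        for j in range(p):
            idx = np.arange(p) != j
            W11 = W[np.ix_(idx, idx)]
            s12 = S[idx, j]
            beta = _lasso_cd(W11, s12, rho, inner_tol, inner_max_iter)
            betas[idx, j] = beta
            w12 = W11 @ beta
            W[idx, j] = w12
            W[j, idx] = w12
        delta = np.abs(W - W_old)[mask].mean()
        scale = np.abs(S)[mask].mean()
        if delta <= tol * max(scale, 1e-12):
            break
    # recover the precision matrix from W and the final lasso coefficients
    theta = np.zeros((p, p))
    for j in range(p):
        idx = np.arange(p) != j
        beta = betas[idx, j]
        denom = W[j, j] - W[idx, j] @ beta
        theta[j, j] = 1.0 / denom
        theta[idx, j] = -beta * theta[j, j]
    return 0.5 * (theta + theta.T)
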