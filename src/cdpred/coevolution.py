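"""Direct-coupling estimation by sparse inverse covariance.

The pipeline follows the PSICOV family: encode each alignment column as a
21-state categorical variable (20 amino acids + gap), form
sequence-weighted single- and pair-site frequencies with a pseudocount,
build the (21 L) x (21 L) sample covariance, shrink it to positive
definiteness, estimate a sparse precision matrix by solving the graphical
lasso, and score each residue pair by the L1 norm of its 20 x 20
inter-position precision block (gap state excluded), optionally with the
average product correction (APC) to remove background signal.

A strong off-diagonal block between columns i and j indicates a direct
statistical dependency that transitive correlation cannot explain — the
coevolutionary signature of a 3D contact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso
from sklearn.exceptions import ConvergenceWarning

from .msa import Msa, N_STATES, identity_matrix

DEFAULT_RHO = 0.02
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class FrequencyTables:
    """Sequence-weighted single- and pair-site frequencies."""

    f1: np.ndarray          # (L_cols, q) single-site frequencies
    f2: np.ndarray          # (q*L_cols, q*L_cols) pair frequencies, block layout
    weights: np.ndarray     # per-row weights
    pseudocount: float
    n_states: int = N_STATES

    @property
    def n_columns(self) -> int:
        return self.f1.shape[0]


@dataclass
class CovarianceModel:
    """Shrunk empirical covariance of the one-hot encoded alignment."""

    matrix: np.ndarray
    pseudocount: float
    shrinkage: float
    n_states: int = N_STATES

    def column_index(self, position: int, state: int) -> int:
        """Flat row/column index of (alignment column, residue state)."""
        return position * self.n_states + state


@dataclass
class PrecisionModel:
    """Sparse inverse covariance estimate and its penalised objective."""

    matrix: np.ndarray
    rho: float
    objective: float
    converged: bool
    n_states: int = N_STATES


@dataclass
class CouplingMatrix:
    """L x L symmetric per-pair coupling scores."""

    scores: np.ndarray
    apc_applied: bool
    raw_scores: np.ndarray = field(default=None, repr=False)

    @property
    def L(self) -> int:
        return self.scores.shape[0]


def _one_hot(codes: np.ndarray, q: int) -> np.ndarray:
    M, W = codes.shape
    out = np.zeros((M, W * q), dtype=np.float64)
    flat = np.arange(W) * q + codes
    rows = np.repeat(np.arange(M), W)
    out[rows, flat.ravel()] = 1.0
    return out


def sequence_weights(msa: Msa, identity_threshold: float = 0.8) -> np.ndarray:
    """Per-row weight 1 / (rows within >= threshold identity, inclusive)."""
    ident = identity_matrix(msa)
    neighbours = (ident >= identity_threshold).sum(axis=1)
    return 1.0 / neighbours


def weighted_frequencies(
    msa: Msa,
    identity_threshold: float = 0.8,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> FrequencyTables:
    """Weighted single/pair frequency tables with uniform-pseudocount mixing.

    Each row contributes weight 1/n where n is the number of rows at least
    ``identity_threshold`` identical to it (itself included), damping
    phylogenetic redundancy. Frequencies are mixed toward the uniform
    distribution over the 21 states with mixing fraction
    pc / (pc + total weight), so pair tables still marginalise exactly to
    the single-site tables.
    """
    if msa.M < 2:
        raise ValueError("need at least 2 rows to estimate frequencies")
    q = N_STATES
    codes = msa.encoded()
    W_cols = codes.shape[1]
    w = sequence_weights(msa, identity_threshold)
    wtot = w.sum()
    onehot = _one_hot(codes, q)
    # observed weighted frequencies
    f1_obs = (w[:, None] * onehot).sum(axis=0).reshape(W_cols, q) / wtot
    f2_obs = (onehot * w[:, None]).T @ onehot / wtot

    gap_state = q - 1
    all_gap = np.where(f1_obs[:, gap_state] >= 1.0 - 1e-12)[0]
    if all_gap.size:
        warnings.warn(
            f"columns {all_gap.tolist()} are entirely gaps; their "
            "frequencies are pure pseudocount",
            stacklevel=2,
        )

    lam = pseudocount / (pseudocount + wtot) if pseudocount > 0 else 0.0
    f1 = (1.0 - lam) * f1_obs + lam / q
    f2 = (1.0 - lam) * f2_obs + lam / (q * q)
    # same-column blocks are diagonal by construction; mix them toward
    # the single-site uniform so that marginalisation stays exact
    for c in range(W_cols):
        blk = slice(c * q, (c + 1) * q)
        f2[blk, blk] = np.diag((1.0 - lam) * np.diag(f2_obs[blk, blk]) + lam / q)
    return FrequencyTables(f1=f1, f2=f2, weights=w, pseudocount=pseudocount)


def sample_covariance(freqs: FrequencyTables) -> CovarianceModel:
    """Covariance Cov[(i,a),(j,b)] = f_ij(a,b) - f_i(a) f_j(b)."""
    flat1 = freqs.f1.reshape(-1)
    cov = freqs.f2 - np.outer(flat1, flat1)
    cov = 0.5 * (cov + cov.T)
    return CovarianceModel(matrix=cov, pseudocount=freqs.pseudocount, shrinkage=0.0,
                           n_states=freqs.n_states)


def shrink_to_spd(
    cov: CovarianceModel, step: float = 0.05, min_eig: float = 1e-8
) -> CovarianceModel:
    """Shrink toward the diagonal until the covariance is positive definite.

    Returns (1-s) C + s diag(C) with the smallest s on the grid
    {0, step, 2 step, ..., 1} whose smallest eigenvalue exceeds
    ``min_eig``; s is recorded on the returned model.
    """
    C = cov.matrix
    diag = np.diag(np.diag(C))
    s = 0.0
    while s <= 1.0 + 1e-12:
        shrunk = (1.0 - s) * C + s * diag
        if np.linalg.eigvalsh(shrunk).min() > min_eig:
            return CovarianceModel(
                matrix=shrunk,
                pseudocount=cov.pseudocount,
                shrinkage=round(s, 10),
                n_states=cov.n_states,
            )
        s = round(s + step, 10)
    raise np.linalg.LinAlgError(
        "covariance diagonal is not positive; cannot reach positive definiteness"
    )


def glasso_objective(theta: np.ndarray, S: np.ndarray, rho: float) -> float:
    """Penalised negative log-likelihood -logdet(T) + tr(S T) + rho ||offdiag T||_1."""
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return np.inf
    l1 = np.abs(theta).sum() - np.abs(np.diag(theta)).sum()
    return float(-logdet + np.trace(S @ theta) + rho * l1)


def glasso_precision(
    cov: CovarianceModel,
    rho: float = DEFAULT_RHO,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> PrecisionModel:
    """Estimate the sparse precision matrix by the graphical lasso.

    The L1 penalty applies to off-diagonal entries. On non-convergence the
    best iterate is returned with ``converged=False``.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    S = cov.matrix
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        _, prec = _sk_graphical_lasso(
            S, alpha=rho, tol=tol, max_iter=max_iter, enet_tol=1e-7
        )
        if any(issubclass(c.category, ConvergenceWarning) for c in caught):
            converged = False
    prec = 0.5 * (prec + prec.T)
    return PrecisionModel(
        matrix=prec,
        rho=rho,
        objective=glasso_objective(prec, S, rho),
        converged=converged,
        n_states=cov.n_states,
    )


def coupling_scores(precision: PrecisionModel, apc: bool = True) -> CouplingMatrix:
    """Per-pair coupling scores from inter-position precision blocks.

    raw(i, j) is the L1 norm of the 20 x 20 block between positions i and
    j with the gap state excluded. With ``apc`` the average product
    correction raw(i,j) - rowmean_i rowmean_j / grandmean is subtracted,
    removing per-position background coupling levels.
    """
    q = precision.n_states
    p = precision.matrix.shape[0]
    L = p // q
    if L < 2:
        return CouplingMatrix(scores=np.zeros((L, L)), apc_applied=apc,
                              raw_scores=np.zeros((L, L)))
    # |theta| reshaped to (L, q, L, q); drop the gap state before the norm
    absA = np.abs(precision.matrix).reshape(L, q, L, q)
    raw = absA[:, : q - 1, :, : q - 1].sum(axis=(1, 3))
    np.fill_diagonal(raw, 0.0)
    raw = 0.5 * (raw + raw.T)
    if not apc:
        return CouplingMatrix(scores=raw, apc_applied=False, raw_scores=raw)
    rowmean = raw.sum(axis=1) / (L - 1)
    grandmean = raw.sum() / (L * (L - 1))
    if grandmean <= 0:
        corrected = raw.copy()
    else:
        corrected = raw - np.outer(rowmean, rowmean) / grandmean
    np.fill_diagonal(corrected, 0.0)
    return CouplingMatrix(scores=corrected, apc_applied=True, raw_scores=raw)


def msa_couplings(
    msa: Msa,
    rho: float = DEFAULT_RHO,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    identity_threshold: float = 0.8,
    apc: bool = True,
    tol: float = 1e-3,
    max_iter: int = 100,
) -> CouplingMatrix:
    """Full alignment-to-couplings pipeline with default settings."""
    freqs = weighted_frequencies(msa, identity_threshold, pseudocount)
    cov = shrink_to_spd(sample_covariance(freqs))
    prec = glasso_precision(cov, rho=rho, tol=tol, max_iter=max_iter)
    return coupling_scores(prec, apc=apc)
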