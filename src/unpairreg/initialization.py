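"""Initial expression estimate and initial cis-regulatory coefficients.

Before the covariance regression has anything to iterate on, a rough paired
expression matrix is built for the ATAC cells by combining two marginals:
the mean expression of each gene (from the RNA cells) and a per-ATAC-cell
relative depth factor derived from the number of accessible REs. Regressing
that rough estimate on accessibility, gene by gene on the 200 kb support,
gives the starting coefficients beta0.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .types import CellMatrix, CisRegCoefficients, DistancePairs

__all__ = ["depth_factors", "initial_expression_estimate", "initial_coefficients"]


def depth_factors(nnz: np.ndarray) -> np.ndarray:
    """Relative cell-depth factors exp((10/M) * nnz_k) / mean_k' exp(...).

    M is the maximum per-cell nonzero count, so the exponent lies in (0, 10]
    and the factors have mean exactly 1.
    """
    nnz = np.asarray(nnz, dtype=np.float64)
    m = nnz.max()
    if m <= 0:
        raise ValueError("all-zero accessibility matrix has no depth signal")
    f = np.exp(10.0 * nnz / m)
    return f / f.mean()


def initial_expression_estimate(
    O: CellMatrix, E: CellMatrix, depth_counts: np.ndarray | None = None
) -> np.ndarray:
    """Rough n1 x p2 expression estimate: depth factor x gene mean.

    ``depth_counts`` overrides the per-cell nonzero-RE counts; pass the
    pre-imputation counts when O has been imputed (imputation saturates the
    nonzero pattern and erases the depth signal).
    """
    if depth_counts is None:
        depth_counts = (O.values != 0).sum(axis=1)
    if len(depth_counts) != O.n_cells:
        raise ValueError("depth_counts length does not match O")
    factors = depth_factors(np.asarray(depth_counts))
    gene_means = E.values.mean(axis=0)
    return np.outer(factors, gene_means)


def initial_coefficients(
    O: CellMatrix,
    e_hat: np.ndarray,
    pairs: DistancePairs,
    gene_ids: np.ndarray,
    ridge_eps: float = 1e-6,
) -> CisRegCoefficients:
    """Per-gene masked least squares of the rough estimate on accessibility.

    For gene j with nearby-RE set S_j, solves
    (O_Sj' O_Sj + eps I) b = O_Sj' e_hat_j with eps = ridge_eps * trace/|S_j|
    for numerical stability; genes with empty S_j get zero columns. Entries
    outside the distance support are exactly zero.
    """
    if e_hat.shape != (O.n_cells, pairs.n_genes):
        raise ValueError("e_hat shape does not match (n1, p2)")
    groups = pairs.gene_groups()
    data: list[np.ndarray] = []
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    V = O.values
    for j, s in enumerate(groups):
        if s.size == 0:
            continue
        Os = V[:, s]
        gram = Os.T @ Os
        eps = ridge_eps * np.trace(gram) / s.size
        b = np.linalg.solve(
            gram + eps * np.eye(s.size), Os.T @ e_hat[:, j]
        )
        data.append(b)
        rows.append(s)
        cols.append(np.full(s.size, j, dtype=np.int64))
    if data:
        mat = sp.csc_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(pairs.n_res, pairs.n_genes),
        )
    else:
        mat = sp.csc_matrix((pairs.n_res, pairs.n_genes))
    return CisRegCoefficients(mat, O.feature_ids, gene_ids)
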