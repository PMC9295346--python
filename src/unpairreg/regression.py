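"""Covariance-matrix regression for unpaired cis-regulatory inference.

With accessibility O (n1 x p1) and expression E (n2 x p2) measured on
different cells of the same population, the paired regression E = O beta + eps
cannot be fit directly. Its second-moment consequence can:

    E'E = beta' O'O beta + eps'eps

so the gene-gene inner-product matrix Y = E'E is modeled as a quadratic of
the RE-RE inner-product matrix G = O'O. Writing X = beta'G linearizes the
problem to Y ~ X beta, which is solved one gene (one column of beta) at a
time as a small ridge regression over the REs within 200 kb of the gene,
with penalty weights exp(d_ij/d0) that grow with genomic distance. After
each column update the corresponding row of X is refreshed (Gauss-Seidel),
and sweeps over all genes repeat until the coefficients stabilize.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .initialization import initial_coefficients, initial_expression_estimate
from .types import CellMatrix, CisRegCoefficients, DistancePairs

__all__ = [
    "CovarianceSystem",
    "build_covariance_system",
    "update_gene_column",
    "UnpairReg",
    "fit_cis_regression",
    "predict_expression",
]


@dataclass
class CovarianceSystem:
    """Y = E'E (p2 x p2), G = O'O (p1 x p1), working matrix X = beta'G (p2 x p1)."""

    Y: np.ndarray
    G: np.ndarray
    X: np.ndarray


def build_covariance_system(
    E: CellMatrix, O: CellMatrix, beta0: CisRegCoefficients
) -> CovarianceSystem:
    """Raw (uncentered) inner products of the preprocessed matrices."""
    if beta0.shape != (O.n_features, E.n_features):
        raise ValueError(
            f"beta0 shape {beta0.shape} does not match (p1={O.n_features}, p2={E.n_features})"
        )
    Y = E.values.T @ E.values
    G = O.values.T @ O.values
    X = np.asarray((beta0.matrix.T @ G))
    return CovarianceSystem(Y=Y, G=G, X=X)


def update_gene_column(
    sys: CovarianceSystem, j: int, s: np.ndarray, a_hat: np.ndarray, lam: float
) -> tuple[np.ndarray, bool]:
    """Closed-form weighted-ridge update of beta[:, j] on its support S_j.

    Solves (x'x + lam diag(a^2)) b = x' Y[:, j] where x = X[:, S_j] and a
    holds the decay weights exp(d/d0) of gene j's nearby REs. Returns the new
    coefficients and a flag that is True when the system was singular and a
    pseudo-inverse solve was used. Does not touch X; callers refresh row j.
    """
    xh = sys.X[:, s]
    lhs = xh.T @ xh + lam * np.diag(a_hat**2)
    rhs = xh.T @ sys.Y[:, j]
    try:
        b = np.linalg.solve(lhs, rhs)
        singular = not np.all(np.isfinite(b))
    except np.linalg.LinAlgError:
        singular = True
    if singular:
        b = np.linalg.lstsq(lhs, rhs, rcond=None)[0]
    return b, singular


def _per_gene_support(pairs: DistancePairs) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-gene RE index sets S_j and matching distances, stable order."""
    order = np.lexsort((pairs.re_index, pairs.gene_index))
    g = pairs.gene_index[order]
    r = pairs.re_index[order]
    d = pairs.distance[order]
    bounds = np.searchsorted(g, np.arange(pairs.n_genes + 1))
    supports = [r[bounds[j] : bounds[j + 1]] for j in range(pairs.n_genes)]
    dists = [d[bounds[j] : bounds[j + 1]] for j in range(pairs.n_genes)]
    return supports, dists


class UnpairReg(BaseEstimator):
    """Cis-regulatory coefficient estimator for unpaired multi-omic data.

    Parameters
    ----------
    lam : float, default 1e7
        Weight of the distance-decay ridge penalty.
    d0 : float, default 10_000
        Decay length (bp) of the penalty weights exp(d/d0).
    n_sweeps : int, default 3
        Maximum full passes over genes.
    tol : float, default 1e-4
        Early-stop threshold on the max relative coefficient change per sweep.
    ridge_eps : float, default 1e-6
        Relative ridge used when initializing beta0 by masked least squares.

    Attributes
    ----------
    beta_ : CisRegCoefficients
        Fitted sparse p1 x p2 coefficient matrix (support within 200 kb mask).
    objective_trace_ : pandas.DataFrame
        Columns (sweep, objective, max_delta); objective is
        ||Y - beta'G beta||_F^2 + lam ||A * beta||_F^2.
    n_sweeps_ : int
        Sweeps actually performed.
    n_singular_updates_ : int
        Column updates that required a pseudo-inverse fallback.
    """

    def __init__(
        self,
        lam: float = 1e7,
        d0: float = 10_000.0,
        n_sweeps: int = 3,
        tol: float = 1e-4,
        ridge_eps: float = 1e-6,
    ):
        self.lam = lam
        self.d0 = d0
        self.n_sweeps = n_sweeps
        self.tol = tol
        self.ridge_eps = ridge_eps

    def fit(
        self,
        O: CellMatrix,
        E: CellMatrix,
        pairs: DistancePairs,
        depth_counts: np.ndarray | None = None,
        beta0: CisRegCoefficients | None = None,
    ) -> "UnpairReg":
        """Fit beta from preprocessed accessibility O and expression E.

        ``depth_counts`` are per-ATAC-cell raw nonzero-RE counts used by the
        depth-based initialization; ``beta0`` overrides the initialization
        entirely.
        """
        if pairs.n_res != O.n_features or pairs.n_genes != E.n_features:
            raise ValueError("pairs dims do not match O/E features")
        if beta0 is None:
            e_hat = initial_expression_estimate(O, E, depth_counts=depth_counts)
            beta0 = initial_coefficients(
                O, e_hat, pairs, E.feature_ids, ridge_eps=self.ridge_eps
            )
        system = build_covariance_system(E, O, beta0)
        supports, dists = _per_gene_support(pairs)
        weights = [np.exp(d / self.d0) for d in dists]
        b0 = beta0.matrix.tocsc()
        cols: list[np.ndarray] = [
            b0[:, j].toarray().ravel()[s] if s.size else np.empty(0)
            for j, s in enumerate(supports)
        ]
        self.n_singular_updates_ = 0
        trace: list[tuple[int, float, float]] = []
        scale = max(max((np.abs(c).max() for c in cols if c.size), default=0.0), 1e-300)
        for sweep in range(self.n_sweeps):
            max_delta = 0.0
            for j, s in enumerate(supports):
                if s.size == 0:
                    continue
                b, singular = update_gene_column(system, j, s, weights[j], self.lam)
                self.n_singular_updates_ += int(singular)
                delta = np.abs(b - cols[j]).max() / scale
                max_delta = max(max_delta, delta)
                cols[j] = b
                system.X[j, :] = b @ system.G[s, :]
            obj = self._objective(system, supports, cols, weights)
            trace.append((sweep + 1, obj, max_delta))
            scale = max(max((np.abs(c).max() for c in cols if c.size), default=0.0), 1e-300)
            if max_delta < self.tol:
                break
        self.n_sweeps_ = len(trace)
        self.objective_trace_ = pd.DataFrame(
            trace, columns=["sweep", "objective", "max_delta"]
        )
        self.beta_ = _assemble(cols, supports, pairs, O.feature_ids, E.feature_ids)
        return self

    def _objective(self, system, supports, cols, weights) -> float:
        """Eq-style objective ||Y - X beta||_F^2 + lam ||A*beta||_F^2 (X = beta'G)."""
        p2 = system.Y.shape[0]
        fit_term = 0.0
        pen = 0.0
        for j, s in enumerate(supports):
            if s.size == 0:
                resid = system.Y[:, j]
            else:
                resid = system.Y[:, j] - system.X[:, s] @ cols[j]
                pen += float(np.sum((weights[j] * cols[j]) ** 2))
            fit_term += float(resid @ resid)
        return fit_term + self.lam * pen

    def predict(self, O: CellMatrix) -> np.ndarray:
        """Predicted expression for accessibility cells: E_hat = O beta."""
        if not hasattr(self, "beta_"):
            raise RuntimeError("estimator is not fitted")
        return predict_expression(O, self.beta_)


def _assemble(cols, supports, pairs, re_ids, gene_ids) -> CisRegCoefficients:
    data, rows, cidx = [], [], []
    for j, s in enumerate(supports):
        if s.size == 0:
            continue
        data.append(cols[j])
        rows.append(s)
        cidx.append(np.full(s.size, j, dtype=np.int64))
    if data:
        mat = sp.csc_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cidx))),
            shape=(pairs.n_res, pairs.n_genes),
        )
    else:
        mat = sp.csc_matrix((pairs.n_res, pairs.n_genes))
    return CisRegCoefficients(mat, re_ids, gene_ids)


def fit_cis_regression(
    O: CellMatrix,
    E: CellMatrix,
    pairs: DistancePairs,
    lam: float = 1e7,
    d0: float = 10_000.0,
    n_sweeps: int = 3,
    depth_counts: np.ndarray | None = None,
    beta0: CisRegCoefficients | None = None,
) -> UnpairReg:
    """Functional wrapper over :class:`UnpairReg`."""
    return UnpairReg(lam=lam, d0=d0, n_sweeps=n_sweeps).fit(
        O, E, pairs, depth_counts=depth_counts, beta0=beta0
    )


def predict_expression(O: CellMatrix, beta: CisRegCoefficients) -> np.ndarray:
    """E_hat = O beta (n1 x p2); genes with empty support give zero columns."""
    if O.n_features != beta.shape[0]:
        raise ValueError("O features do not match beta rows")
    return np.asarray(O.values @ beta.matrix.toarray())
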