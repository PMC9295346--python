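"""Clustering and co-embedding of unpaired accessibility and expression cells.

Three pieces: modularity (Louvain-family) clustering of cells on their
standardized PC embedding; coupled nonnegative matrix factorization of the
two modalities with the fitted cis-regulatory coefficients as the coupling
matrix; and a CCA co-embedding that places both cell sets in one space by
treating the shared features as samples and the cells of each view as
variables, so the two views may have different numbers of cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .evaluation import knn_graph
from .preprocessing import Embedding
from .types import CellMatrix, CisRegCoefficients

__all__ = [
    "louvain_cluster",
    "CoupledFactors",
    "CoupledNMF",
    "coupled_nmf",
    "cca_coembed",
]


def louvain_cluster(
    emb: Embedding, resolution: float = 1.0, k: int = 15, seed: int = 0
) -> np.ndarray:
    """Graph-modularity community labels on the standardized PC embedding.

    Each PC is rescaled to unit standard deviation, a kNN graph is built on
    the standardized coordinates, and communities are found at the given
    resolution. Deterministic for a fixed seed.
    """
    coords = emb.coords if isinstance(emb, Embedding) else np.asarray(emb, dtype=float)
    if coords.shape[0] <= k:
        raise ValueError(f"need more than k={k} cells")
    sd = coords.std(axis=0)
    sd[sd == 0] = 1.0
    z = coords / sd
    adj = knn_graph(z, k).tocoo()
    mask = adj.row < adj.col
    g = igraph.Graph(
        n=coords.shape[0], edges=list(zip(adj.row[mask], adj.col[mask]))
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership, dtype=np.int64)


@dataclass
class CoupledFactors:
    """Nonnegative factors of the coupled factorization (features x r, r x cells)."""

    W1: np.ndarray
    H1: np.ndarray
    W2: np.ndarray
    H2: np.ndarray
    objective_trace: pd.DataFrame

    def atac_labels(self) -> np.ndarray:
        return np.argmax(self.H1, axis=0)

    def rna_labels(self) -> np.ndarray:
        return np.argmax(self.H2, axis=0)


class CoupledNMF(BaseEstimator):
    """Coupled NMF of accessibility and expression with a cis-regulatory coupling.

    Minimizes
        1/2 ||O - W1 H1||_F^2 + lambda1/2 ||E - W2 H2||_F^2
        - lambda2 tr(W2' A W1) + mu (||W1||_F^2 + ||W2||_F^2)
    over nonnegative factors, where O is p1 x n1 (features x cells), E is
    p2 x n2, and A is p2 x p1. The coupling matrix is the fitted beta
    (negative entries clipped to zero, then transposed), so factors that pair
    regulating REs with their target genes are rewarded.

    Multiplicative updates (KKT-derived):
        W1 <- W1 * (O H1' + lambda2 A' W2) / (W1 H1 H1' + 2 mu W1)
        H1 <- H1 * (W1' O) / (W1' W1 H1)
        W2 <- W2 * (lambda1 E H2' + lambda2 A W1) / (lambda1 W2 H2 H2' + 2 mu W2)
        H2 <- H2 * (W2' E) / (W2' W2 H2)

    The trace coupling rewards unbounded growth of W1/W2 through each other,
    so the ridge must dominate the feedback loop: keep
    lambda2 * sigma_max(A) below roughly 2 * mu or the iteration diverges.
    """

    def __init__(
        self,
        r: int = 7,
        lambda1: float = 1.0,
        lambda2: float = 0.5,
        mu: float = 1.0,
        max_iter: int = 200,
        seed: int = 0,
    ):
        self.r = r
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.mu = mu
        self.max_iter = max_iter
        self.seed = seed

    def _objective(self, O, E, A, W1, H1, W2, H2) -> float:
        r1 = O - W1 @ H1
        r2 = E - W2 @ H2
        return float(
            0.5 * np.sum(r1 * r1)
            + 0.5 * self.lambda1 * np.sum(r2 * r2)
            - self.lambda2 * np.trace(W2.T @ A @ W1)
            + self.mu * (np.sum(W1 * W1) + np.sum(W2 * W2))
        )

    def fit(self, O: CellMatrix, E: CellMatrix, beta: CisRegCoefficients) -> "CoupledNMF":
        """Factorize both modalities; O and E are CellMatrix (cells x features)."""
        Om = O.values.T  # p1 x n1
        Em = E.values.T  # p2 x n2
        if beta.shape != (Om.shape[0], Em.shape[0]):
            raise ValueError("beta dims do not match O/E features")
        if self.r > min(Om.shape + Em.shape):
            raise ValueError("r exceeds a matrix dimension")
        A = np.clip(beta.matrix.toarray(), 0.0, None).T  # p2 x p1
        rng = np.random.default_rng(self.seed)
        eps = 1e-12

        def init(M):
            scale = np.sqrt(M.mean() / self.r) if M.mean() > 0 else 1.0
            return (
                scale * rng.uniform(0.1, 1.0, (M.shape[0], self.r)),
                scale * rng.uniform(0.1, 1.0, (self.r, M.shape[1])),
            )

        W1, H1 = init(Om)
        W2, H2 = init(Em)
        trace = [(0, self._objective(Om, Em, A, W1, H1, W2, H2))]
        for it in range(1, self.max_iter + 1):
            W1 *= (Om @ H1.T + self.lambda2 * (A.T @ W2)) / (
                W1 @ (H1 @ H1.T) + 2 * self.mu * W1 + eps
            )
            H1 *= (W1.T @ Om) / (W1.T @ W1 @ H1 + eps)
            W2 *= (self.lambda1 * (Em @ H2.T) + self.lambda2 * (A @ W1)) / (
                self.lambda1 * (W2 @ (H2 @ H2.T)) + 2 * self.mu * W2 + eps
            )
            H2 *= (W2.T @ Em) / (W2.T @ W2 @ H2 + eps)
            trace.append((it, self._objective(Om, Em, A, W1, H1, W2, H2)))
        self.factors_ = CoupledFactors(
            W1=W1,
            H1=H1,
            W2=W2,
            H2=H2,
            objective_trace=pd.DataFrame(trace, columns=["iteration", "objective"]),
        )
        return self


def coupled_nmf(
    O: CellMatrix,
    E: CellMatrix,
    beta: CisRegCoefficients,
    r: int = 7,
    lambda1: float = 1.0,
    lambda2: float = 0.5,
    mu: float = 1.0,
    max_iter: int = 200,
    seed: int = 0,
) -> CoupledFactors:
    """Functional wrapper over :class:`CoupledNMF`."""
    est = CoupledNMF(
        r=r, lambda1=lambda1, lambda2=lambda2, mu=mu, max_iter=max_iter, seed=seed
    ).fit(O, E, beta)
    return est.factors_


def cca_coembed(
    view_a: np.ndarray,
    view_b: np.ndarray,
    n_components: int = 10,
    standardize: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CCA co-embedding of two cell sets sharing a feature dimension.

    ``view_a`` (n_a cells x p features) and ``view_b`` (n_b x p) are treated
    with cells as variables and the p shared features as observations. Each
    feature is standardized within its view (so no single high-magnitude
    gene dominates), and the cross-covariance matrix between the two cell
    sets is decomposed by SVD — the diagonal-CCA formulation used for
    single-cell co-embedding, which stays well-posed when cells outnumber
    features. The left/right singular vectors, scaled by their singular
    values, are the per-cell coordinates in the shared space.

    Returns (coords_a, coords_b, correlations); the canonical correlations
    are the empirical correlations of the paired canonical variate profiles,
    in descending order, each in [0, 1].
    """
    Za = np.asarray(view_a, dtype=np.float64).T.copy()  # p x n_a
    Zb = np.asarray(view_b, dtype=np.float64).T.copy()
    if Za.shape[0] != Zb.shape[0]:
        raise ValueError("views must share the feature dimension")
    p = Za.shape[0]
    if n_components > min(Za.shape[1], Zb.shape[1], p):
        raise ValueError("n_components exceeds a shared dimension")
    if standardize:
        for Z in (Za, Zb):
            Z -= Z.mean(axis=1, keepdims=True)
            sd = Z.std(axis=1)
            sd[sd == 0] = 1.0
            Z /= sd[:, None]
    Za = Za - Za.mean(axis=0, keepdims=True)
    Zb = Zb - Zb.mean(axis=0, keepdims=True)
    K = Za.T @ Zb / max(p - 1, 1)
    U, s, Vt = np.linalg.svd(K, full_matrices=False)
    k = n_components
    coords_a = U[:, :k] * s[:k]
    coords_b = Vt[:k].T * s[:k]
    corrs = np.zeros(k)
    for i in range(k):
        fa = Za @ U[:, i]
        gb = Zb @ Vt[i]
        na, nb = np.linalg.norm(fa), np.linalg.norm(gb)
        if na > 0 and nb > 0:
            # SVD convention makes fa.gb = s_i >= 0, so this lies in [0, 1]
            corrs[i] = np.clip(fa @ gb / (na * nb), 0.0, 1.0)
    return coords_a, coords_b, corrs
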