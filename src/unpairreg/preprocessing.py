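"""Pre-processing of single-cell count matrices.

The pipeline is: drop features active in fewer than 1% of cells, scale each
cell to the median sequencing depth, embed cells with PCA of the
log1p-transformed values keeping components 2..20 (the first component
tracks depth), and denoise by averaging each cell with its K nearest
neighbors in the embedding. Imputation is applied to the depth-normalized
counts — not their logarithm — so the matrices the regression stage calls
E and O stay on the count scale, where the linear model E = O beta lives;
the log transform is used only to compute well-behaved cell-cell distances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from .types import CellMatrix

__all__ = [
    "Embedding",
    "filter_inactive_features",
    "normalize_log",
    "pca_embed",
    "knn_impute",
    "preprocess",
]


@dataclass
class Embedding:
    """Cells x dims PCA coordinate matrix restricted to components 2..20."""

    coords: np.ndarray
    dims: tuple[int, int]
    rank_deficient: bool = False

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


def filter_inactive_features(m: CellMatrix, min_frac: float = 0.01) -> CellMatrix:
    """Drop features nonzero in fewer than ceil(min_frac * n_cells) cells."""
    if not (0 < min_frac < 1):
        raise ValueError("min_frac must lie in (0, 1)")
    threshold = math.ceil(min_frac * m.n_cells)
    nnz = (m.values != 0).sum(axis=0)
    keep = nnz >= threshold
    if not keep.any():
        raise ValueError("all features removed by activity filter")
    return CellMatrix(m.values[:, keep], m.cell_ids, m.feature_ids[keep], m.role)


def normalize_depth(m: CellMatrix) -> CellMatrix:
    """Scale each cell's counts to the median sequencing depth."""
    depth = m.values.sum(axis=1)
    if (depth == 0).any():
        raise ValueError("zero-depth cell cannot be normalized")
    target = np.median(depth)
    return m.with_values(m.values * (target / depth)[:, None])


def normalize_log(m: CellMatrix) -> CellMatrix:
    """Scale each cell to the median depth, then log1p."""
    scaled = normalize_depth(m)
    return scaled.with_values(np.log1p(scaled.values))


def pca_embed(m: CellMatrix, pca_dims: tuple[int, int] = (2, 20)) -> Embedding:
    """Centered PCA scores for components pca_dims[0]..pca_dims[1] (1-based).

    Component signs are fixed so the largest-magnitude loading of each
    component is positive. If the data rank is below the requested range the
    available components are returned and the embedding is flagged.
    """
    lo, hi = pca_dims
    if m.n_cells <= hi:
        hi = min(hi, m.n_cells - 1)
    centered = m.values - m.values.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: largest-|loading| positive
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    scores = u * s[None, :] * flip[None, :]
    tol = max(centered.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    last = min(hi, scores.shape[1])
    coords = scores[:, lo - 1 : last]
    deficient = rank < hi
    if deficient:
        warnings.warn(
            f"data rank {rank} below requested component {hi}; trailing "
            "components are numerically null",
            RuntimeWarning,
            stacklevel=2,
        )
    return Embedding(coords=coords, dims=(lo, last), rank_deficient=deficient)


def knn_neighbor_indices(emb: Embedding, k: int) -> np.ndarray:
    """Indices (n x k) of the k nearest cells (self included, ties by index)."""
    d = cdist(emb.coords, emb.coords)
    # stable argsort -> distance ties broken by cell index
    return np.argsort(d, axis=1, kind="stable")[:, :k]


def knn_impute(m: CellMatrix, emb: Embedding, k: int = 100) -> CellMatrix:
    """Replace each cell by the unweighted mean of its k nearest cells.

    Distances are Euclidean in the PCA embedding; the neighbor set includes
    the cell itself, so k=1 is the identity.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > m.n_cells:
        raise ValueError(f"k={k} exceeds number of cells {m.n_cells}")
    if emb.n_cells != m.n_cells:
        raise ValueError("embedding and matrix disagree on cell count")
    idx = knn_neighbor_indices(emb, k)
    n = m.n_cells
    rows = np.repeat(np.arange(n), k)
    avg = sp.csr_matrix(
        (np.full(n * k, 1.0 / k), (rows, idx.ravel())), shape=(n, n)
    )
    return m.with_values(avg @ m.values)


def preprocess(
    m: CellMatrix,
    min_frac: float = 0.01,
    k_impute: int = 100,
    pca_dims: tuple[int, int] = (2, 20),
) -> tuple[CellMatrix, Embedding, np.ndarray]:
    """Full pre-processing chain for one modality.

    Returns the imputed depth-normalized count matrix, the PCA embedding
    (computed on log1p values), and the per-cell nonzero feature counts of
    the filtered raw matrix (used downstream as an ATAC cell-depth proxy).
    """
    filtered = filter_inactive_features(m, min_frac=min_frac)
    raw_nnz = (filtered.values != 0).sum(axis=1)
    scaled = normalize_depth(filtered)
    emb = pca_embed(scaled.with_values(np.log1p(scaled.values)), pca_dims=pca_dims)
    k = min(k_impute, scaled.n_cells)
    imputed = knn_impute(scaled, emb, k=k)
    return imputed, emb, raw_nnz
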