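"""Evaluation metrics for predicted expression, coefficients, and embeddings.

Profile similarities (Pearson/Spearman/cosine/RMSE) are computed per cell
(across genes) or per gene (across cells). Alignment error counts, for each
cell, how many other cells are strictly closer than its true cross-matrix
match, in both matching directions. AUPR is reported per genomic-distance
bin of the RE-gene pairs, scoring by |beta|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse import csgraph
from scipy.spatial.distance import cdist
from scipy.stats import rankdata, ttest_1samp
from sklearn.metrics import (
    adjusted_rand_score,
    average_precision_score,
    normalized_mutual_info_score,
    silhouette_samples,
)

from .preprocessing import Embedding
from .types import CisRegCoefficients, DistancePairs

__all__ = [
    "MetricReport",
    "profile_similarity",
    "alignment_error",
    "silhouette_index",
    "clustering_agreement",
    "graph_connectivity",
    "DISTANCE_BINS",
    "aupr_distance_bins",
    "paired_difference_test",
    "masked_coefficient_pcc",
]


@dataclass
class MetricReport:
    """Per-profile metric values; NaN marks undefined (constant-vector) profiles."""

    metric: str
    axis: str
    values: np.ndarray

    @property
    def mean(self) -> float:
        """Mean over defined profiles."""
        return float(np.nanmean(self.values))


def _rowwise_pcc(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("ij,ij->i", a, b) / (na * nb)
    r[(na == 0) | (nb == 0)] = np.nan
    return r


def profile_similarity(
    X: np.ndarray, Y: np.ndarray, axis: str = "cell", metric: str = "pcc"
) -> MetricReport:
    """Per-cell (axis='cell', across genes) or per-gene similarity between X and Y.

    Metrics: 'pcc', 'spearman', 'cosine', 'rmse'. Correlations of constant
    profiles are undefined and reported as NaN (excluded from the mean).
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch {X.shape} vs {Y.shape}")
    if axis not in ("cell", "gene"):
        raise ValueError("axis must be 'cell' or 'gene'")
    if axis == "gene":
        X, Y = X.T, Y.T
    if metric == "pcc":
        vals = _rowwise_pcc(X, Y)
    elif metric == "spearman":
        vals = _rowwise_pcc(
            rankdata(X, axis=1).astype(float), rankdata(Y, axis=1).astype(float)
        )
    elif metric == "cosine":
        na = np.linalg.norm(X, axis=1)
        nb = np.linalg.norm(Y, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.einsum("ij,ij->i", X, Y) / (na * nb)
        vals[(na == 0) | (nb == 0)] = np.nan
    elif metric == "rmse":
        vals = np.sqrt(np.mean((X - Y) ** 2, axis=1))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return MetricReport(metric=metric, axis=axis, values=vals)


def alignment_error(X_pred: np.ndarray, Y_true: np.ndarray) -> np.ndarray:
    """Per-cell count of cells strictly closer than the true match.

    For cell k: the number of cells i with d(x_k, y_i) < d(x_k, y_k) plus
    the number with d(x_i, y_k) < d(x_k, y_k) (Euclidean over the shared
    gene space). 0 means a perfect match; the maximum is 2(n-1).
    """
    X_pred = np.asarray(X_pred, dtype=np.float64)
    Y_true = np.asarray(Y_true, dtype=np.float64)
    if X_pred.shape != Y_true.shape:
        raise ValueError("matrices must share the cell and gene sets")
    n = X_pred.shape[0]
    if n < 2:
        raise ValueError("alignment error needs at least 2 cells")
    D = cdist(X_pred, Y_true)
    diag = np.diag(D)
    n1 = (D < diag[:, None]).sum(axis=1)
    n2 = (D < diag[None, :]).sum(axis=0)
    return (n1 + n2).astype(np.int64)


def silhouette_index(emb: Embedding, labels: np.ndarray) -> np.ndarray:
    """Per-cell silhouette with cosine distance on the PC embedding."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 labels")
    return silhouette_samples(emb.coords, labels, metric="cosine")


def clustering_agreement(labels_a: np.ndarray, labels_b: np.ndarray) -> dict[str, float]:
    """NMI (arithmetic-mean normalization) and ARI between two labelings."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.size == 0 or labels_a.shape != labels_b.shape:
        raise ValueError("labelings must be nonempty and equally sized")
    return {
        "nmi": float(
            normalized_mutual_info_score(labels_a, labels_b, average_method="arithmetic")
        ),
        "ari": float(adjusted_rand_score(labels_a, labels_b)),
    }


def knn_graph(coords: np.ndarray, k: int) -> sp.csr_matrix:
    """Symmetric (union) kNN adjacency, self excluded, ties broken by index."""
    n = coords.shape[0]
    k = min(k, n - 1)
    D = cdist(coords, coords)
    np.fill_diagonal(D, np.inf)
    idx = np.argsort(D, axis=1, kind="stable")[:, :k]
    rows = np.repeat(np.arange(n), k)
    adj = sp.csr_matrix((np.ones(n * k), (rows, idx.ravel())), shape=(n, n))
    adj = adj.maximum(adj.T)
    return adj


def graph_connectivity(emb, cell_types: np.ndarray, k: int = 15) -> float:
    """Mean over labels of the largest-connected-component fraction.

    A kNN graph (Euclidean) is built on the full co-embedding; for each cell
    type the induced subgraph's largest connected component is divided by the
    label size. 1 means every type forms a single connected component.
    """
    coords = emb.coords if isinstance(emb, Embedding) else np.asarray(emb, dtype=np.float64)
    cell_types = np.asarray(cell_types)
    if len(cell_types) != coords.shape[0]:
        raise ValueError("label length does not match embedding")
    adj = knn_graph(coords, k)
    fracs = []
    for c in np.unique(cell_types):
        members = np.flatnonzero(cell_types == c)
        sub = adj[np.ix_(members, members)]
        _, comp = csgraph.connected_components(sub, directed=False)
        largest = np.bincount(comp).max()
        fracs.append(largest / members.size)
    return float(np.mean(fracs))


DISTANCE_BINS: tuple[tuple[str, float, float], ...] = (
    ("0-3k", 0.0, 3_000.0),
    ("3-10k", 3_000.0, 10_000.0),
    ("10-20k", 10_000.0, 20_000.0),
    ("20-50k", 20_000.0, 50_000.0),
    ("50-100k", 50_000.0, 100_000.0),
    ("100-150k", 100_000.0, 150_000.0),
)


def aupr_distance_bins(
    beta: CisRegCoefficients,
    pairs: DistancePairs,
    truth_links: set[tuple[int, int]],
    bins=DISTANCE_BINS,
) -> pd.DataFrame:
    """Area under the precision-recall curve per genomic-distance bin.

    Scores are |beta| on the pair support; positives are (re_index,
    gene_index) pairs in ``truth_links``. Bins with no positives yield NaN.
    AUPR uses step-wise integration (sum of precision x recall increments).
    """
    b = beta.matrix.tocsc()
    scores = np.abs(np.asarray(b[pairs.re_index, pairs.gene_index]).ravel())
    is_pos = np.fromiter(
        ((r, g) in truth_links for r, g in zip(pairs.re_index, pairs.gene_index)),
        dtype=bool,
        count=len(pairs),
    )
    out = []
    for name, lo, hi in bins:
        mask = (pairs.distance >= lo) & (pairs.distance < hi)
        n_pos = int(is_pos[mask].sum())
        if n_pos == 0 or mask.sum() == 0:
            out.append((name, int(mask.sum()), n_pos, np.nan))
            continue
        aupr = float(average_precision_score(is_pos[mask], scores[mask]))
        out.append((name, int(mask.sum()), n_pos, aupr))
    return pd.DataFrame(out, columns=["bin", "n_pairs", "n_positives", "aupr"])


def paired_difference_test(metric_a: np.ndarray, metric_b: np.ndarray) -> dict[str, float]:
    """One-sample t-test on the paired differences a - b against zero mean."""
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired vectors must match and have n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        # degenerate: no spread in the differences
        if np.allclose(d.mean(), 0.0):
            return {"mean_diff": 0.0, "t": 0.0, "p": 1.0, "degenerate": True}
        t = np.inf if d.mean() > 0 else -np.inf
        return {"mean_diff": float(d.mean()), "t": float(t), "p": 0.0, "degenerate": True}
    res = ttest_1samp(d, 0.0)
    return {
        "mean_diff": float(d.mean()),
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "degenerate": False,
    }


def masked_coefficient_pcc(
    beta_hat: CisRegCoefficients, beta_true: CisRegCoefficients, pairs: DistancePairs
) -> float:
    """Pearson correlation of estimated vs true beta over the distance mask."""
    bh = beta_hat.matrix.tocsc()
    bt = beta_true.matrix.tocsc()
    x = np.asarray(bh[pairs.re_index, pairs.gene_index]).ravel()
    y = np.asarray(bt[pairs.re_index, pairs.gene_index]).ravel()
    return float(np.corrcoef(x, y)[0, 1])
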