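"""Domain containers shared across the package.

Conventions
-----------
* Cell matrices are stored cells x features (dense float64); on disk the
  10x orientation (features x cells) is used, see :mod:`unpairreg.io`.
* Genomic coordinates are 0-based; RE intervals are half-open BED intervals
  and the RE anchor is the interval midpoint.
* The cis-regulatory coefficient matrix ``beta`` is p1 (REs) x p2 (genes),
  sparse, with support restricted to same-chromosome RE-gene pairs within
  ``max_distance`` of the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CellMatrix",
    "DistancePairs",
    "CisRegCoefficients",
    "HyperParams",
    "make_regions_table",
    "make_genes_table",
]

REGION_COLUMNS = ("re_id", "chrom", "start", "end", "center")
GENE_COLUMNS = ("gene_id", "chrom", "tss", "strand")


def make_regions_table(
    re_id: Sequence[str],
    chrom: Sequence[str],
    start: Sequence[int],
    end: Sequence[int],
) -> pd.DataFrame:
    """Build a validated regulatory-element table.

    The anchor used for RE-gene distances is ``center = floor((start+end)/2)``.
    Raises ``ValueError`` on duplicate ids or malformed intervals.
    """
    df = pd.DataFrame(
        {
            "re_id": np.asarray(re_id, dtype=object),
            "chrom": np.asarray(chrom, dtype=object),
            "start": np.asarray(start, dtype=np.int64),
            "end": np.asarray(end, dtype=np.int64),
        }
    )
    if df["re_id"].duplicated().any():
        raise ValueError("duplicate RE ids")
    bad = df["start"] >= df["end"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"malformed interval for {df['re_id'].iloc[i]}: "
            f"start {df['start'].iloc[i]} >= end {df['end'].iloc[i]}"
        )
    if (df["start"] < 0).any():
        raise ValueError("negative start coordinate")
    df["center"] = (df["start"] + df["end"]) // 2
    return df


def make_genes_table(
    gene_id: Sequence[str],
    chrom: Sequence[str],
    tss: Sequence[int],
    strand: Sequence[str],
) -> pd.DataFrame:
    """Build a validated gene/TSS table (strand in {+,-})."""
    df = pd.DataFrame(
        {
            "gene_id": np.asarray(gene_id, dtype=object),
            "chrom": np.asarray(chrom, dtype=object),
            "tss": np.asarray(tss, dtype=np.int64),
            "strand": np.asarray(strand, dtype=object),
        }
    )
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids")
    if (df["tss"] < 0).any():
        raise ValueError("negative TSS position")
    ok = df["strand"].isin(["+", "-"])
    if not ok.all():
        bad = df.loc[~ok, "strand"].iloc[0]
        raise ValueError(f"unknown strand symbol {bad!r}")
    return df


@dataclass
class CellMatrix:
    """Nonnegative cells x features matrix with identifiers.

    ``role`` is "accessibility" (the O matrix) or "expression" (the E matrix).
    """

    values: np.ndarray
    cell_ids: np.ndarray
    feature_ids: np.ndarray
    role: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        if self.role not in ("accessibility", "expression"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, p = self.values.shape
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.feature_ids) != p:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {p} columns")
        if self.values.size and self.values.min() < 0:
            raise ValueError("negative entries in cell matrix")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "CellMatrix":
        return CellMatrix(
            self.values.copy(), self.cell_ids.copy(), self.feature_ids.copy(), self.role
        )

    def with_values(self, values: np.ndarray) -> "CellMatrix":
        return CellMatrix(values, self.cell_ids, self.feature_ids, self.role)


@dataclass
class DistancePairs:
    """Sparse same-chromosome RE-gene pairs with genomic distance <= cutoff."""

    re_index: np.ndarray
    gene_index: np.ndarray
    distance: np.ndarray
    cutoff: float
    n_res: int
    n_genes: int

    def __post_init__(self) -> None:
        self.re_index = np.asarray(self.re_index, dtype=np.int64)
        self.gene_index = np.asarray(self.gene_index, dtype=np.int64)
        self.distance = np.asarray(self.distance, dtype=np.float64)
        if not (len(self.re_index) == len(self.gene_index) == len(self.distance)):
            raise ValueError("triplet arrays differ in length")
        if self.distance.size and self.distance.max() > self.cutoff:
            raise ValueError("pair distance exceeds cutoff")

    def __len__(self) -> int:
        return len(self.distance)

    def support(self) -> sp.csc_matrix:
        """Boolean p1 x p2 support mask."""
        return sp.csc_matrix(
            (np.ones(len(self), dtype=bool), (self.re_index, self.gene_index)),
            shape=(self.n_res, self.n_genes),
        )

    def gene_groups(self) -> list[np.ndarray]:
        """Per-gene arrays of nearby-RE indices (the sets S_j), gene order."""
        order = np.argsort(self.gene_index, kind="stable")
        groups: list[np.ndarray] = [np.empty(0, dtype=np.int64) for _ in range(self.n_genes)]
        if len(self) == 0:
            return groups
        g_sorted = self.gene_index[order]
        r_sorted = self.re_index[order]
        bounds = np.searchsorted(g_sorted, np.arange(self.n_genes + 1))
        for j in range(self.n_genes):
            groups[j] = r_sorted[bounds[j] : bounds[j + 1]]
        return groups

    def distance_matrix(self) -> sp.csc_matrix:
        """Sparse p1 x p2 matrix of distances on the pair support."""
        return sp.csc_matrix(
            (self.distance, (self.re_index, self.gene_index)),
            shape=(self.n_res, self.n_genes),
        )


@dataclass
class CisRegCoefficients:
    """Sparse p1 x p2 cis-regulatory coefficient matrix beta with ids."""

    matrix: sp.csc_matrix
    re_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = sp.csc_matrix(self.matrix)
        self.re_ids = np.asarray(self.re_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        p1, p2 = self.matrix.shape
        if len(self.re_ids) != p1 or len(self.gene_ids) != p2:
            raise ValueError("id lengths do not match matrix dims")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def triplets(self) -> pd.DataFrame:
        """Triplet (re_id, gene_id, value) view, deterministic column-major order."""
        coo = self.matrix.tocoo()
        order = np.lexsort((coo.row, coo.col))
        return pd.DataFrame(
            {
                "re_id": self.re_ids[coo.row[order]],
                "gene_id": self.gene_ids[coo.col[order]],
                "value": coo.data[order],
            }
        )


@dataclass
class HyperParams:
    """Model hyper-parameters and their defaults.

    lam
        Ridge weight on the distance-decay penalty (default 1e7).
    d0
        Decay length scale (bp) of the penalty weights exp(d/d0).
    max_distance
        Hard cutoff D0 (bp) beyond which coefficients are fixed to zero.
    k_impute
        Neighborhood size for kNN-average imputation.
    lambda1
        Weight of the cell-cell covariance term in expression fine-tuning.
    n_sweeps
        Full passes over genes in the covariance-regression solver.
    pca_dims
        1-based inclusive range of retained principal components; the first
        PC is excluded because it tracks sequencing depth.
    """

    lam: float = 1e7
    d0: float = 10_000.0
    max_distance: float = 200_000.0
    k_impute: int = 100
    lambda1: float = 0.5
    n_sweeps: int = 3
    pca_dims: tuple[int, int] = (2, 20)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lam, self.d0, self.max_distance, self.lambda1) < 0:
            raise ValueError("hyper-parameters must be nonnegative")
        if self.k_impute <= 0 or self.n_sweeps <= 0:
            raise ValueError("k_impute and n_sweeps must be positive")
        lo, hi = self.pca_dims
        if lo < 2 or hi < lo:
            raise ValueError("pca_dims must be a range starting at component >= 2")

    def replace(self, **kw) -> "HyperParams":
        return replace(self, **kw)
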