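"""Genomic distance structure between regulatory elements and genes.

Cross-chromosome RE-gene distances are treated as infinite, which is
represented by absence from :class:`~unpairreg.types.DistancePairs`; there is
no sentinel value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .types import DistancePairs

__all__ = ["build_distance_pairs", "decay_weights"]


def build_distance_pairs(
    regions: pd.DataFrame, genes: pd.DataFrame, max_distance: float = 200_000.0
) -> DistancePairs:
    """Enumerate same-chromosome RE-gene pairs with |center - tss| <= max_distance.

    The RE anchor is the interval midpoint; the gene anchor is the TSS
    (strand does not change the absolute distance).
    """
    if len(regions) == 0 or len(genes) == 0:
        raise ValueError("regions and genes tables must be nonempty")
    re_idx_parts: list[np.ndarray] = []
    gene_idx_parts: list[np.ndarray] = []
    dist_parts: list[np.ndarray] = []
    centers = regions["center"].to_numpy(dtype=np.int64)
    tss = genes["tss"].to_numpy(dtype=np.int64)
    gene_chrom = genes["chrom"].to_numpy(dtype=object)
    for chrom, sub in regions.groupby("chrom", sort=False):
        gmask = np.flatnonzero(gene_chrom == chrom)
        if gmask.size == 0:
            continue
        ridx = sub.index.to_numpy(dtype=np.int64)
        d = np.abs(centers[ridx][:, None] - tss[gmask][None, :])
        keep = d <= max_distance
        rr, gg = np.nonzero(keep)
        re_idx_parts.append(ridx[rr])
        gene_idx_parts.append(gmask[gg])
        dist_parts.append(d[rr, gg])
    if re_idx_parts:
        re_index = np.concatenate(re_idx_parts)
        gene_index = np.concatenate(gene_idx_parts)
        distance = np.concatenate(dist_parts).astype(np.float64)
    else:
        re_index = np.empty(0, dtype=np.int64)
        gene_index = np.empty(0, dtype=np.int64)
        distance = np.empty(0, dtype=np.float64)
    # deterministic order: by gene, then RE
    order = np.lexsort((re_index, gene_index))
    return DistancePairs(
        re_index=re_index[order],
        gene_index=gene_index[order],
        distance=distance[order],
        cutoff=float(max_distance),
        n_res=len(regions),
        n_genes=len(genes),
    )


def decay_weights(pairs: DistancePairs, d0: float) -> sp.csc_matrix:
    """Penalty weight matrix A with A_ij = exp(d_ij / d0) on the pair support.

    The penalty grows with distance so that long-range coefficients are
    shrunk harder than proximal ones.
    """
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    w = np.exp(pairs.distance / d0)
    return sp.csc_matrix(
        (w, (pairs.re_index, pairs.gene_index)), shape=(pairs.n_res, pairs.n_genes)
    )
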