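"""Readers and writers for the on-disk formats the tool touches.

Count matrices follow the 10x convention: Matrix Market coordinate file in
features x cells orientation plus ``features.tsv`` / ``barcodes.tsv`` line
lists. In memory, matrices are cells x rows (see :class:`CellMatrix`).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .types import (
    CellMatrix,
    CisRegCoefficients,
    make_genes_table,
    make_regions_table,
)

__all__ = [
    "read_cell_matrix",
    "write_cell_matrix",
    "read_regions_bed",
    "write_regions_bed",
    "read_genes_table",
    "write_genes_table",
    "read_coefficients",
    "write_coefficients",
]


def _read_lines(path: str) -> np.ndarray:
    with open(path) as fh:
        return np.asarray([ln.rstrip("\n").split("\t")[0] for ln in fh if ln.strip()], dtype=object)


def read_cell_matrix(
    matrix_path: str, features_path: str, barcodes_path: str, role: str
) -> CellMatrix:
    """Read a 10x-style sparse count matrix as a cells x features CellMatrix."""
    mat = sp.csr_matrix(scipy.io.mmread(matrix_path))
    features = _read_lines(features_path)
    barcodes = _read_lines(barcodes_path)
    p, n = mat.shape
    if len(features) != p:
        raise ValueError(f"{len(features)} features listed but matrix has {p} rows")
    if len(barcodes) != n:
        raise ValueError(f"{len(barcodes)} barcodes listed but matrix has {n} columns")
    if mat.nnz and mat.data.min() < 0:
        raise ValueError("negative entries in count matrix")
    return CellMatrix(mat.T.toarray(), barcodes, features, role)


def write_cell_matrix(m: CellMatrix, matrix_path: str, features_path: str, barcodes_path: str) -> None:
    """Write a CellMatrix in the 10x on-disk layout (features x cells)."""
    mat = sp.csc_matrix(m.values.T)
    mat.sort_indices()
    scipy.io.mmwrite(matrix_path, mat)
    with open(features_path, "w") as fh:
        fh.writelines(f"{f}\n" for f in m.feature_ids)
    with open(barcodes_path, "w") as fh:
        fh.writelines(f"{b}\n" for b in m.cell_ids)


def read_regions_bed(path: str) -> pd.DataFrame:
    """Read RE intervals from BED3+ (0-based half-open); ids from column 4 if present."""
    rows = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln or ln.startswith(("#", "track", "browser")):
                continue
            parts = ln.split("\t")
            if len(parts) < 3:
                raise ValueError(f"BED line with <3 fields: {ln!r}")
            rows.append(parts)
    chrom = [r[0] for r in rows]
    start = [int(r[1]) for r in rows]
    end = [int(r[2]) for r in rows]
    re_id = [
        r[3] if len(r) > 3 else f"{r[0]}:{r[1]}-{r[2]}" for r in rows
    ]
    return make_regions_table(re_id, chrom, start, end)


def write_regions_bed(regions: pd.DataFrame, path: str) -> None:
    regions[["chrom", "start", "end", "re_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_genes_table(path: str) -> pd.DataFrame:
    """Read a gene table TSV with header columns gene_id, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    missing = {"gene_id", "chrom", "tss", "strand"} - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns {sorted(missing)}")
    return make_genes_table(df["gene_id"], df["chrom"], df["tss"], df["strand"])


def write_genes_table(genes: pd.DataFrame, path: str) -> None:
    genes[["gene_id", "chrom", "tss", "strand"]].to_csv(path, sep="\t", index=False)


def write_coefficients(beta: CisRegCoefficients, path: str) -> None:
    """Write beta as a triplet TSV (re_id, gene_id, value); lossless round trip."""
    beta.triplets().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_coefficients(
    path: str, re_ids: np.ndarray, gene_ids: np.ndarray
) -> CisRegCoefficients:
    """Read a triplet TSV back into a sparse matrix over the given id universes."""
    df = pd.read_csv(path, sep="\t", dtype={"re_id": str, "gene_id": str})
    re_ids = np.asarray(re_ids, dtype=object)
    gene_ids = np.asarray(gene_ids, dtype=object)
    re_pos = {r: i for i, r in enumerate(re_ids)}
    gene_pos = {g: j for j, g in enumerate(gene_ids)}
    try:
        rows = np.asarray([re_pos[r] for r in df["re_id"]], dtype=np.int64)
        cols = np.asarray([gene_pos[g] for g in df["gene_id"]], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"coefficient file references unknown id {e.args[0]!r}") from e
    mat = sp.csc_matrix(
        (df["value"].to_numpy(dtype=np.float64), (rows, cols)),
        shape=(len(re_ids), len(gene_ids)),
    )
    return CisRegCoefficients(mat, re_ids, gene_ids)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
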