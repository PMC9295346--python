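"""End-to-end workflow: preprocess both modalities, fit, predict, fine-tune."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .finetune import CovarianceFineTuner
from .genome import build_distance_pairs
from .preprocessing import Embedding, preprocess
from .regression import UnpairReg
from .types import CellMatrix, CisRegCoefficients, DistancePairs, HyperParams

__all__ = ["PipelineResult", "run_pipeline", "subset_to_kept"]


@dataclass
class PipelineResult:
    """Everything a downstream evaluation or export needs."""

    model: UnpairReg
    beta: CisRegCoefficients
    pairs: DistancePairs
    E_hat: np.ndarray  # n1 x p2 regression prediction (O beta)
    E_hat_finetuned: np.ndarray
    O: CellMatrix  # preprocessed (imputed) accessibility
    E: CellMatrix  # preprocessed (imputed) expression
    O_embedding: Embedding
    E_embedding: Embedding
    regions: pd.DataFrame  # kept REs, matrix order
    genes: pd.DataFrame  # kept genes, matrix order
    re_keep: np.ndarray  # positions of kept REs in the input O columns
    gene_keep: np.ndarray  # positions of kept genes in the input E columns
    finetuner: CovarianceFineTuner


def _reorder(table: pd.DataFrame, id_col: str, ids: np.ndarray) -> pd.DataFrame:
    pos = {v: i for i, v in enumerate(table[id_col])}
    idx = [pos[v] for v in ids]
    return table.iloc[idx].reset_index(drop=True)


def run_pipeline(
    O_raw: CellMatrix,
    E_raw: CellMatrix,
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    params: HyperParams | None = None,
    finetune: bool = True,
) -> PipelineResult:
    """Run the full method on raw count matrices.

    Both matrices are filtered (features active in < 1% of cells dropped),
    depth-normalized, log1p-transformed, and kNN-imputed on their PC
    embeddings; the regression is fit on the 200 kb distance support of the
    surviving features; expression for the ATAC cells is predicted as
    O beta and optionally refined by covariance-preserving fine-tuning.
    """
    params = params or HyperParams()
    O_imp, O_emb, O_nnz = preprocess(
        O_raw, k_impute=params.k_impute, pca_dims=params.pca_dims
    )
    E_imp, E_emb, _ = preprocess(
        E_raw, k_impute=params.k_impute, pca_dims=params.pca_dims
    )
    regions_kept = _reorder(regions, "re_id", O_imp.feature_ids)
    genes_kept = _reorder(genes, "gene_id", E_imp.feature_ids)
    pairs = build_distance_pairs(regions_kept, genes_kept, params.max_distance)

    model = UnpairReg(
        lam=params.lam, d0=params.d0, n_sweeps=params.n_sweeps
    ).fit(O_imp, E_imp, pairs, depth_counts=O_nnz)
    e_hat = model.predict(O_imp)

    tuner = CovarianceFineTuner(lambda1=params.lambda1).fit(E_imp, O_imp)
    e_hat_ft = tuner.transform(e_hat) if finetune else e_hat

    o_pos = {v: i for i, v in enumerate(O_raw.feature_ids)}
    e_pos = {v: i for i, v in enumerate(E_raw.feature_ids)}
    re_keep = np.asarray([o_pos[v] for v in O_imp.feature_ids], dtype=np.int64)
    gene_keep = np.asarray([e_pos[v] for v in E_imp.feature_ids], dtype=np.int64)
    return PipelineResult(
        model=model,
        beta=model.beta_,
        pairs=pairs,
        E_hat=e_hat,
        E_hat_finetuned=e_hat_ft,
        O=O_imp,
        E=E_imp,
        O_embedding=O_emb,
        E_embedding=E_emb,
        regions=regions_kept,
        genes=genes_kept,
        re_keep=re_keep,
        gene_keep=gene_keep,
        finetuner=tuner,
    )


def subset_to_kept(
    beta_true: CisRegCoefficients, result: PipelineResult
) -> CisRegCoefficients:
    """Restrict a ground-truth beta to the features the pipeline kept."""
    sub = beta_true.matrix.tocsr()[result.re_keep][:, result.gene_keep]
    return CisRegCoefficients(
        sub, result.O.feature_ids, result.E.feature_ids
    )
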