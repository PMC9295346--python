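"""Synthetic unpaired multi-omic data with known cis-regulatory truth.

The generator draws the model class the regression assumes: K cell types
with type-specific RE accessibility programs, per-cell gamma-distributed
sequencing depth, Poisson accessibility counts, expression driven linearly
by accessibility through a sparse distance-decaying true beta
(E = O beta + noise), Poisson expression counts, and Bernoulli dropout
calibrated so the final zero fraction of each matrix hits a target rate.
Cells are then split disjointly into an ATAC-only and an RNA-only set, so no
cell carries both modalities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .types import CellMatrix, CisRegCoefficients, make_genes_table, make_regions_table

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "UnpairedDataset",
    "simulate_genome_layout",
    "simulate_true_coefficients",
    "simulate_paired_truth",
    "apply_dropout",
    "split_unpaired",
    "simulate_unpaired_dataset",
    "random_celltype_config",
    "minor_population_config",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic unpaired dataset.

    Defaults correspond to the main simulation setting: five equally
    proportioned cell types, 1000 cells per modality, 500 genes each with
    2-6 candidate REs within 200 kb of its TSS, expression built as
    E = O beta + noise, and (optionally) dropout calibrated to a target
    overall zero fraction.
    """

    n_celltypes: int = 5
    proportions: tuple[float, ...] | None = None  # None -> equal
    n_atac_cells: int = 1000
    n_rna_cells: int = 1000
    n_genes: int = 500
    res_per_gene: tuple[int, int] = (2, 6)
    max_distance: float = 200_000.0
    gene_spacing: int = 1_000_000
    genes_per_chrom: int = 50
    re_width: int = 500
    decay_length: float = 50_000.0  # bp scale of the true-effect decay
    active_re_prob: float = 0.7  # chance a candidate RE truly regulates
    type_effect_sd: float = 1.0  # lognormal sd of type-specific activity
    depth_shape: float = 10.0  # gamma shape of per-cell depth (mean 1)
    atac_scale: float = 1.0  # Poisson rate scale for accessibility counts
    rna_scale: float = 1.0  # Poisson rate scale for expression counts
    noise_sd: float = 0.2  # additive biological noise on expression
    dropout_target: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.proportions is not None:
            props = np.asarray(self.proportions, dtype=float)
            if len(props) != self.n_celltypes or not np.isclose(props.sum(), 1.0):
                raise ValueError("proportions must have n_celltypes entries summing to 1")
        if self.dropout_target is not None and not (0 <= self.dropout_target < 1):
            raise ValueError("dropout_target must lie in [0, 1)")

    def effective_proportions(self) -> np.ndarray:
        if self.proportions is None:
            return np.full(self.n_celltypes, 1.0 / self.n_celltypes)
        return np.asarray(self.proportions, dtype=float)


@dataclass
class SimulationTruth:
    """Ground truth for all (paired) cells before the unpaired split."""

    beta_true: CisRegCoefficients
    O_counts: np.ndarray  # n x p1 pre-dropout accessibility counts
    E_counts: np.ndarray  # n x p2 pre-dropout expression counts
    E_noiseless: np.ndarray  # n x p2, exactly O_counts @ beta_true
    labels: np.ndarray  # n cell-type labels
    depth: np.ndarray  # per-cell depth factors


@dataclass
class UnpairedDataset:
    """Observed unpaired data plus everything needed for evaluation."""

    O: CellMatrix  # ATAC cells, post-dropout counts
    E: CellMatrix  # RNA cells, post-dropout counts
    regions: pd.DataFrame
    genes: pd.DataFrame
    beta_true: CisRegCoefficients
    truth: SimulationTruth
    atac_cells: np.ndarray  # indices into the paired truth
    rna_cells: np.ndarray
    labels_atac: np.ndarray
    labels_rna: np.ndarray
    # dropout-observed expression counts of the ATAC cells: the Fig-2-style
    # "observed" baseline a prediction should beat (None without dropout)
    E_obs_atac: np.ndarray | None = None

    @property
    def E_noiseless_atac(self) -> np.ndarray:
        """True (noiseless) expression of the ATAC cells — the prediction target."""
        return self.truth.E_noiseless[self.atac_cells]

    @property
    def E_counts_atac(self) -> np.ndarray:
        """Pre-dropout expression counts of the ATAC cells."""
        return self.truth.E_counts[self.atac_cells]


def simulate_genome_layout(cfg: SimulationConfig, rng: np.random.Generator | None = None):
    """Place genes on synthetic chromosomes and assign each its candidate REs.

    Genes sit ``gene_spacing`` apart (far beyond 2 * max_distance), so every
    RE lies within 200 kb of exactly one TSS and chromosomes never share REs.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n_chrom = -(-cfg.n_genes // cfg.genes_per_chrom)
    gene_ids, gene_chrom, gene_tss, gene_strand = [], [], [], []
    re_ids, re_chrom, re_start, re_end = [], [], [], []
    re_gene = []  # designated gene of each candidate RE
    lo, hi = cfg.res_per_gene
    half_w = cfg.re_width // 2
    g = 0
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        for k in range(cfg.genes_per_chrom):
            if g >= cfg.n_genes:
                break
            tss = (k + 1) * cfg.gene_spacing
            gid = f"g{g}"
            gene_ids.append(gid)
            gene_chrom.append(chrom)
            gene_tss.append(tss)
            gene_strand.append("+" if rng.random() < 0.5 else "-")
            n_re = int(rng.integers(lo, hi + 1))
            offsets = rng.integers(
                -int(cfg.max_distance) + half_w, int(cfg.max_distance) - half_w, n_re
            )
            for m, off in enumerate(sorted(offsets)):
                center = tss + int(off)
                re_ids.append(f"re_{gid}_{m}")
                re_chrom.append(chrom)
                re_start.append(center - half_w)
                re_end.append(center + half_w)
                re_gene.append(g)
            g += 1
    regions = make_regions_table(re_ids, re_chrom, re_start, re_end)
    genes = make_genes_table(gene_ids, gene_chrom, gene_tss, gene_strand)
    regions["designated_gene"] = np.asarray(re_gene, dtype=np.int64)
    return regions, genes


def simulate_true_coefficients(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> CisRegCoefficients:
    """Sparse positive true beta with exponential distance decay.

    Each candidate RE of a gene regulates it with probability
    ``active_re_prob`` (at least one per gene); active weights are
    u * exp(-d / decay_length) with u ~ Uniform(0.5, 1.5).
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    tss = genes["tss"].to_numpy()
    centers = regions["center"].to_numpy()
    owner = regions["designated_gene"].to_numpy()
    rows, cols, vals = [], [], []
    for j in range(len(genes)):
        members = np.flatnonzero(owner == j)
        if members.size == 0:
            continue
        active = rng.random(members.size) < cfg.active_re_prob
        if not active.any():
            d_all = np.abs(centers[members] - tss[j])
            active[np.argmin(d_all)] = True
        for i in members[active]:
            d = abs(int(centers[i]) - int(tss[j]))
            w = rng.uniform(0.5, 1.5) * np.exp(-d / cfg.decay_length)
            rows.append(i)
            cols.append(j)
            vals.append(w)
    mat = sp.csc_matrix(
        (np.asarray(vals), (np.asarray(rows), np.asarray(cols))),
        shape=(len(regions), len(genes)),
    )
    return CisRegCoefficients(
        mat, regions["re_id"].to_numpy(object), genes["gene_id"].to_numpy(object)
    )


def _type_counts(n: int, proportions: np.ndarray) -> np.ndarray:
    """Integer label counts by largest remainder; exact for equal splits."""
    raw = proportions * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def simulate_paired_truth(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    beta_true: CisRegCoefficients,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulationTruth:
    """Paired ground-truth counts for n_atac + n_rna cells.

    Accessibility: per-type RE programs (gamma baseline x lognormal type
    effect), per-cell gamma depth with mean 1, Poisson counts. Expression:
    E_noiseless = O beta_true; observed pre-dropout counts are Poisson around
    rna_scale * (E_noiseless + Gaussian noise, clipped at 0).
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    n = cfg.n_atac_cells + cfg.n_rna_cells
    p1, p2 = beta_true.shape
    props = cfg.effective_proportions()
    counts = _type_counts(n, props)
    labels = rng.permutation(np.repeat(np.arange(cfg.n_celltypes), counts))

    base = rng.gamma(2.0, 0.5, p1)
    type_effect = np.exp(cfg.type_effect_sd * rng.standard_normal((cfg.n_celltypes, p1)))
    programs = base[None, :] * type_effect  # K x p1 mean RE activity
    depth = rng.gamma(cfg.depth_shape, 1.0 / cfg.depth_shape, n)
    rates = cfg.atac_scale * depth[:, None] * programs[labels]
    O_counts = rng.poisson(rates).astype(np.float64)

    E_noiseless = O_counts @ beta_true.matrix.toarray()
    E_pre = E_noiseless + cfg.noise_sd * rng.standard_normal(E_noiseless.shape)
    np.clip(E_pre, 0.0, None, out=E_pre)
    E_counts = rng.poisson(cfg.rna_scale * E_pre).astype(np.float64)
    return SimulationTruth(
        beta_true=beta_true,
        O_counts=O_counts,
        E_counts=E_counts,
        E_noiseless=E_noiseless,
        labels=labels,
        depth=depth,
    )


def apply_dropout(m: CellMatrix, q: float, seed: int = 0) -> CellMatrix:
    """Zero entries so the matrix's overall zero fraction reaches q (+-0.01).

    Pre-existing zeros count toward the target: nonzero entries are zeroed
    independently with probability (q - z0) / (1 - z0) where z0 is the
    current zero fraction. If z0 already exceeds q the input is returned
    unchanged with a warning.
    """
    if not (0 <= q < 1):
        raise ValueError("dropout target must lie in [0, 1)")
    z0 = float((m.values == 0).mean())
    if q <= z0:
        if q < z0:
            warnings.warn(
                f"zero fraction {z0:.3f} already exceeds target {q}; no dropout applied",
                RuntimeWarning,
                stacklevel=2,
            )
        return m.copy()
    p = (q - z0) / (1.0 - z0)
    rng = np.random.default_rng(seed)
    keep = rng.random(m.values.shape) >= p
    out = m.values * keep
    out[m.values == 0] = 0.0
    return m.with_values(out)


def split_unpaired(
    truth: SimulationTruth,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint stratified split of the paired cells into ATAC and RNA sets.

    Returns (atac_indices, rna_indices); within each cell type the split
    preserves the ATAC/RNA ratio to within one cell.
    """
    rng = np.random.default_rng(cfg.seed + 3) if rng is None else rng
    n = len(truth.labels)
    if cfg.n_atac_cells + cfg.n_rna_cells > n:
        raise ValueError("requested split exceeds available cells")
    frac = cfg.n_atac_cells / (cfg.n_atac_cells + cfg.n_rna_cells)
    atac, rna = [], []
    for c in np.unique(truth.labels):
        members = rng.permutation(np.flatnonzero(truth.labels == c))
        k = int(round(frac * members.size))
        atac.append(members[:k])
        rna.append(members[k:])
    atac_idx = np.sort(np.concatenate(atac))
    rna_idx = np.sort(np.concatenate(rna))
    # trim rounding drift to the exact requested sizes
    atac_idx = atac_idx[: cfg.n_atac_cells]
    rna_idx = rna_idx[: cfg.n_rna_cells]
    assert np.intersect1d(atac_idx, rna_idx).size == 0
    return atac_idx, rna_idx


def simulate_unpaired_dataset(cfg: SimulationConfig) -> UnpairedDataset:
    """End-to-end generation: layout, truth, split, and calibrated dropout."""
    rng = np.random.default_rng(cfg.seed)
    regions, genes = simulate_genome_layout(cfg, rng)
    beta_true = simulate_true_coefficients(regions, genes, cfg, rng)
    truth = simulate_paired_truth(regions, genes, beta_true, cfg, rng)
    atac_idx, rna_idx = split_unpaired(truth, cfg, rng)
    O = CellMatrix(
        truth.O_counts[atac_idx],
        np.asarray([f"atac_{i}" for i in atac_idx], dtype=object),
        regions["re_id"].to_numpy(object),
        "accessibility",
    )
    E = CellMatrix(
        truth.E_counts[rna_idx],
        np.asarray([f"rna_{i}" for i in rna_idx], dtype=object),
        genes["gene_id"].to_numpy(object),
        "expression",
    )
    E_obs_atac = None
    if cfg.dropout_target is not None:
        O = apply_dropout(O, cfg.dropout_target, seed=cfg.seed + 10)
        E = apply_dropout(E, cfg.dropout_target, seed=cfg.seed + 11)
        obs = CellMatrix(
            truth.E_counts[atac_idx],
            O.cell_ids,
            genes["gene_id"].to_numpy(object),
            "expression",
        )
        E_obs_atac = apply_dropout(obs, cfg.dropout_target, seed=cfg.seed + 12).values
    return UnpairedDataset(
        O=O,
        E=E,
        regions=regions,
        genes=genes,
        beta_true=beta_true,
        truth=truth,
        atac_cells=atac_idx,
        rna_cells=rna_idx,
        labels_atac=truth.labels[atac_idx],
        labels_rna=truth.labels[rna_idx],
        E_obs_atac=E_obs_atac,
    )


def random_celltype_config(seed: int = 0, **kw) -> SimulationConfig:
    """Variant preset: a random number of cell types with random proportions."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(3, 9))
    props = rng.dirichlet(np.full(k, 5.0))
    return SimulationConfig(
        n_celltypes=k, proportions=tuple(props / props.sum()), seed=seed, **kw
    )


def minor_population_config(n_minor: int = 1, minor_frac: float = 0.02, seed: int = 0, **kw) -> SimulationConfig:
    """Variant preset: 1-3 cell types forming a minor population."""
    if not (1 <= n_minor <= 3):
        raise ValueError("n_minor must be 1, 2, or 3")
    k = 5
    major = (1.0 - n_minor * minor_frac) / (k - n_minor)
    props = tuple([minor_frac] * n_minor + [major] * (k - n_minor))
    return SimulationConfig(n_celltypes=k, proportions=props, seed=seed, **kw)
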