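# unpairreg

Cis-regulatory inference and gene-expression prediction from **unpaired**
single-cell multi-omic data.

Many tissues are profiled with scATAC-seq (chromatin accessibility) on one
set of cells and scRNA-seq (gene expression) on a *different* set of cells
from the same population. No cell carries both measurements, so the natural
regression linking regulatory elements (REs) to target genes (TGs),

    E = O β + ε,

cannot be fit directly — O (n₁ cells × p₁ REs) and E (n₂ cells × p₂ genes)
have no rows in common. `unpairreg` estimates β anyway, from second moments:
the gene–gene matrix Y = EᵀE is a quadratic of the RE–RE matrix G = OᵀO,

    EᵀE = βᵀ OᵀO β + εᵀε,

and both sides are computable from unpaired data. The estimator solves

    min‖EᵀE − βᵀOᵀOβ‖² + λ‖A∘β‖²,  A_ij = exp(d_ij / d₀),

where d_ij is the genomic distance from RE *i*'s midpoint to gene *j*'s TSS;
β_ij is fixed to 0 beyond 200 kb or across chromosomes, and the exponential
penalty (λ = 10⁷, d₀ = 10 kb by default) encodes the distance decay of
cis-regulation. A fast per-gene ridge scheme (linearizing with X = βᵀG)
solves the problem a column at a time. The fitted β predicts expression for
ATAC-only cells (Ê = Oβ), which a covariance-preserving multiplicative
fine-tuning step then refines. The package also ships the surrounding
workflow: 10x-style matrix I/O, kNN-average imputation, the full metric
suite (cell/gene-level correlations, alignment error, silhouette, NMI/ARI,
graph connectivity, distance-binned AUPR), CCA co-embedding plus CoupledNMF
with β as the coupling matrix, and a synthetic-data generator with known
ground truth.

Intended users: computational biologists integrating unpaired scATAC/scRNA
data who want interpretable RE→gene coefficients rather than a black-box
embedding, and methods developers who need a tested reference pipeline with
a ground-truth simulator.

## Worked example

Simulate an unpaired dataset (300 ATAC + 300 RNA cells, 120 genes, 80%
dropout in both modalities), fit, and evaluate against the stored truth:

```bash
unpairreg simulate --out data --atac-cells 300 --rna-cells 300 \
    --genes 120 --dropout 0.8 --seed 7
unpairreg fit --data data --out run --k-impute 30 --seed 7
unpairreg evaluate --data data --run run --out metrics
```

`metrics/similarity.tsv` then contains (numbers from this exact command):

```
metric  axis    mean
pcc     cell    0.729455685044154
pcc     gene    0.194806621680601
spearman        cell    0.5944873851416833
...
```

and `metrics/coefficient_pcc.tsv`:

```
metric  value
coefficient_pcc 0.194646
```

Reading: per cell, the predicted expression profile correlates 0.73 on
average with that cell's true (noiseless) expression across genes even
though 80% of all counts were zeroed — cell identity and depth are
recovered well. The per-gene correlation across cells (0.19) and the
correlation between estimated and true coefficients (0.19) are much lower:
at this dropout and problem size, variation *within* a gene across cells is
dominated by accessibility shot noise that no unpaired method can see.
`metrics/alignment_error.tsv` reports, per cell, how many other cells sit
closer to its prediction than its true match (0 = perfect alignment).

The same objects are available as a library — estimator classes in the
scikit-learn style:

```python
from unpairreg import SimulationConfig, simulate_unpaired_dataset, run_pipeline

ds = simulate_unpaired_dataset(SimulationConfig(dropout_target=0.8, seed=7))
res = run_pipeline(ds.O, ds.E, ds.regions, ds.genes)  # preprocess+fit+finetune
res.beta          # sparse p1 x p2 CisRegCoefficients
res.E_hat         # O @ beta for the ATAC cells
res.model         # fitted UnpairReg estimator (fit/predict/get_params)
```

`unpairreg coembed` adds joint clustering of both cell sets via CCA
co-embedding of predicted and observed expression.

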