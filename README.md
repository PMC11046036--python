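# cellcomm

Inference of **cell-cell communication (CCC) programs across samples** from
single-cell RNA-seq: consensus ligand-receptor scoring per sample, a 4D
communication tensor, non-negative tensor decomposition into interpretable
programs, and pathway-level interpretation of those programs — plus a
simulation framework that quantifies how robust the whole pipeline is to
batch effects and missing data.

## Who this is for

Computational biologists with a multi-sample (multi-patient, multi-condition)
scRNA-seq dataset who want to ask not only *which* ligand-receptor (LR)
interactions occur between cell types, but *how coordinated sets of
interactions vary across samples* — e.g. which communication programs
separate severe from mild disease.

## The method

**Per-sample scoring.** For each sample, expression is library-size
normalized to a target sum and log1p-transformed. For every LR pair
(heteromeric complexes are summarized by their limiting subunit) and every
ordered pair of cell clusters (sender *i*, receiver *j*), six scoring
functions from the literature are computed on cluster summary statistics:

| method | magnitude | specificity |
|---|---|---|
| CellPhoneDB-style | (L + R) / 2 | permutation p |
| Geometric mean | √(L·R) | permutation p |
| CellChat-style | TriMean(L)·TriMean(R) / (Kh + TriMean(L)·TriMean(R)) | permutation p |
| SingleCellSignalR-style | √(LR) / (√(LR) + μ) | — |
| NATMI-style | L·R | (L/ΣL)·(R/ΣR) |
| Connectome-style | L·R | (z_L + z_R)/2 |
| log2FC | — | mean of ligand/receptor log2FC |

where L, R are cluster mean expressions, μ the global matrix mean, z the
z-score of cluster means, and permutation p-values come from shuffling
cluster labels (p = fraction of permuted scores ≥ observed). An interaction
is admitted only if every subunit is expressed in ≥ `expr_prop` (default
0.1) of cells in both clusters.

**Consensus.** Per score family, methods are combined by robust rank
aggregation: normalized ranks r ∈ (0,1], a beta order-statistic probability
P(k-th smallest of m uniforms ≤ r₍ₖ₎) minimized over k, Bonferroni-scaled
by the number of interactions, capped at 1. Small `magnitude_rank` /
`specificity_rank` values mark interactions consistently ranked well.

**Tensor.** Scores (transformed by `1 − x` so higher = stronger) populate a
4D tensor indexed (context, LR pair, sender, receiver). Entries absent from
a context can be **masked** (excluded from the fit) or set to **zero**. A
rank-R non-negative CP decomposition (masked HALS with bounded EM
imputation, multi-restart) yields per-mode loading matrices — each
component is one communication program. Rank is suggested by an elbow rule
on the reconstruction-error curve. Decompositions are compared by the
permutation- and scaling-invariant similarity 1 − CorrIndex.

**Interpretation.** Context loadings are tested between sample groups
(pairwise t-tests, BH correction); LR-pair loadings are interpreted by
preranked GSEA on pathway LR sets (weighted KS statistic, permutation null,
NES) and by footprint regression (joint OLS of loadings on signed pathway
weights, per-pathway t-values). Sender×receiver loading outer products give
factor-specific communication networks.

**Robustness benchmarks.** A generative simulator (gamma gene means,
log-normal library sizes, multiplicative cell-type DE factors, Poisson or
gamma-Poisson noise; even allocation over 6 cell types × 5 samples) plus a
scale-free bipartite LR network (power-law exponent 2, average degree 3)
provide ground truth. Batch effects are injected as per-sample log-normal
gene factors (count-coupled so only the batch effect differs from the gold
standard); missing data by ablating cell types and zeroing LR genes in a
fraction of samples.

## Worked example

```python
import cellcomm as cc

# simulate a 5-sample dataset with a known LR network
from cellcomm.synthetic import SimulationConfig, simulate_counts, attach_lr_network
ds = attach_lr_network(simulate_counts(SimulationConfig(n_genes=600, n_cells=1500, seed=1)),
                       net_seed=1, n_net_genes=80)

adata = cc.qc_normalize(ds.to_anndata())
table = cc.score_by_sample(adata, ds.lr_network.to_resource(),
                           sample_key="sample", groupby="cell_type",
                           spec=cc.MethodSpec(n_perms=0, seed=0))
tensor = cc.build_tensor(table, score_column="magnitude_rank", how="outer")
rank, curve = cc.select_rank_elbow(tensor, max_rank=8, seed=0)
fit = cc.nncp_decompose(tensor, rank=rank, seed=0)
print(len(table), tensor.shape, rank, round(fit.rel_error, 3))
```

prints

```
21294 (5, 120, 6, 6) 5 0.404
```

— 21,294 scored (LR pair, sender, receiver, sample) combinations, a
5-context × 120-pair × 6×6-cell-type tensor, an elbow-suggested rank of 5,
and a rank-5 model reproducing the observed entries with relative error
0.404 (rank scores from unstructured simulated data are far from exactly
low-rank; on real data with shared programs the fit is tighter). The
factor loadings are in `fit.factor_frames()`.

The same pipeline is available from the shell:

```bash
cellcomm simulate --n-genes 600 --n-cells 1500 --seed 1 --output-dir sim/
cellcomm score --expression sim/sim.mtx --metadata sim/sim_metadata.csv \
         --resource sim/sim_lr_resource.csv --n-perms 0 --output-dir out/
cellcomm build-tensor --scores out/score_table.csv --output-dir out/
cellcomm decompose --tensor out/tensor.npz --output-dir out/
cellcomm benchmark --mode missing --seed 0 --output-dir bench/
```

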