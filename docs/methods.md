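# Methods notes

This note records the model assumptions, the parameter choices that
matter, and the numerical decisions taken where the design was genuinely
open. Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`.

## Scoring model and assumptions

All cluster summary statistics (mean, expression proportion, Tukey
trimean, z-score, log2 fold change) are computed on the library-size
normalized, log1p-transformed matrix of one sample at a time; samples
are treated as independent replicates of the same biological system.
The global scalar μ used by the saturating magnitude score is the mean
over the *full* matrix of the sample, not only over resource genes.

Key parameters (defaults):

- `expr_prop = 0.1` — minimum fraction of expressing cells per cluster
  for every subunit; the gate that defines which (pair, sender,
  receiver) triples exist at all.
- `min_cells = 5` — clusters below this size are removed before any
  statistic is computed, including the NATMI-style specificity
  denominators, which sum over retained clusters only.
- `Kh = 0.5` — half-saturation constant of the hill-like communication
  probability; dimensionless because it acts on products of trimeans of
  log-normalized expression.
- `n_perms = 100` — label permutations for specificity p-values. The
  permutation p uses a plain `≥` comparison with no pseudocount, so
  p = 0 is attainable; the permutation stream restarts from the
  configured seed for every sample, making identical samples give
  identical tables.

Ambiguities resolved as package design choices:

- **Complex summarization** uses the *minimum* across subunits for every
  statistic (limiting-subunit convention, consistent with the
  subunit-wise expression gate); a `complex_agg="mean"` switch exists.
- **z-scores** are taken per gene across retained cluster means within a
  sample (ddof = 1); genes constant across clusters get z = 0.
- **log2FC** uses a 1e-9 pseudocount inside each log2 to guard zero
  means.
- **Rank aggregation** Bonferroni-multiplies the minimum beta
  order-statistic probability by the number of interactions *n* (the
  printed convention), with a `bonferroni="m"` switch for the original
  robust-rank-aggregation variant that scales by the number of lists.
  Ties rank by average; magnitudes rank descending, p-values ascending,
  non-permutation specificity scores descending.

## Tensor decomposition

The 4D tensor holds `1 − magnitude_rank` by default, so values lie in
[0, 1] with higher = stronger. Union ("outer") modes mark entries absent
from a context as *missing*; `outer_fraction` prunes elements seen in
fewer than that fraction of contexts (1.0 reproduces the intersection
behaviour).

The non-negative CP fit is hierarchical ALS (HALS) with EM handling of
missing entries: each sweep imputes missing cells with the current
reconstruction. Two numerical safeguards matter in practice:

1. **Bounded imputation.** Imputed values are clipped to the observed
   entry range. Without this, components supported mostly on large
   contiguous missing blocks (exactly what cell-type ablation produces)
   can grow without penalty and the fit diverges — we observed fitted
   component weights four orders of magnitude above the data scale
   before adding the clip. Communication scores are bounded by
   construction, so the clip loses nothing.
2. **Multi-restart.** ALS can land in distinct local minima; all
   benchmark decompositions use the best of 3 restarts (by relative
   error on observed entries). With this, refitting the same tensor from
   different seeds reproduces the same solution to similarity ≈ 1.

Factor columns are reported L2-normalized with the absorbed scale kept
as a per-component weight (sorted descending). The elbow rule picks the
rank maximizing perpendicular distance from the mean error curve to the
chord joining its endpoints, with both axes scaled to [0, 1]; this is a
conventional knee heuristic, documented here because no sharper rule is
prescribed by the method itself. Context order never changes fitted
values, only row order (asserted by a test).

Elements whose fibers contain no observed entry are rejected by default;
the benchmarks opt into `allow_empty_slices=True` so ablated tensors
keep the gold standard's dimensions (such loadings are determined only
by the bounded imputation and are therefore uninformative — acceptable
for similarity comparisons, wrong for interpretation).

## Enrichment

The preranked GSEA statistic is the classical weighted KS running sum
(weight exponent 1, `min_size` 15, 999 permutations by default); the
null permutes set membership over the ranked list, NES divides by the
mean |null ES| of matching sign, and the p-value is the matching-sign
null tail. Ties in loadings keep stable input order. The footprint model
is one joint OLS per factor of the loading vector on all pathway weight
columns plus intercept, unscaled (whether the reference implementation
scales design columns is not documented; fitting unscaled is the
conservative choice and the planted-coefficient tests cover it).
Pathway LR sets require *every* subunit gene of both complexes in the
pathway gene set; weighted sets additionally require sign-coherence of
all participating gene weights and average subunit weights within each
complex before averaging the two sides.

## Simulator

The generator mimics the standard splat-style hierarchy: per-gene base
mean ~ Gamma(shape 0.6, rate 0.3); per-cell library size ~
LogNormal(11, 0.2) (natural-log scale, ≈ 60k counts median); per-cell-
type multiplicative DE factors LogNormal(1.0, 0.4) applied to a random
30% of genes, half inverted (down-regulation); expected counts are the
normalized gene proportions times library size; noise is Poisson
(gamma-Poisson with a biological CV via `bcv > 0`). Cells are allocated
evenly across 6 cell types and 5 samples (defaults 2000 genes × 5000
cells). Gamma/library parameters follow the conventional simulator
defaults; the DE strength was set once so that cell types are clearly
separable (k-means on PCA recovers them with NMI ≈ 1), as in real
well-annotated atlases.

What the simulator does *not* emulate: zero-inflation beyond
Poisson sampling, gene-gene correlation modules, cell-state continua
within a type, and ambient RNA. Benchmarks on it therefore speak to the
pipeline's algebraic robustness (rank stability, masking policy, batch
factors), not to annotation noise on real data.

The LR network generator draws edge endpoints with power-law weights
(w_i ∝ i^(−1/(γ−1)), γ = 2) over 100 ligands × 100 receptors until the
unique-edge count matches an average degree of 3 within 20%; the heavy
tail leaves a substantial fraction of genes unconnected, and those are
excluded from scoring, matching how sparse prior-knowledge resources
behave.

**Batch severity ladder.** Batch effects are per-sample multiplicative
LogNormal(0, σ) gene factors applied to the generative expectations,
with counts coupled to the gold standard by Poisson additivity /
binomial thinning (so severity → 0 reproduces the gold counts exactly).
The ladder σ ∈ {0.1, 0.25, 0.5} was fixed a priori to span the
conventional simulator default (σ ≈ 0.1) up to a deliberately harsh 5×
that value; at σ = 0.5 individual genes routinely shift 2-3 fold
between samples. The harshest rung induces genuine sample-specific
communication structure (the decomposition acquires context-specific
components), so the similarity floor reported by the batch benchmark is
dominated by that rung; the two milder rungs leave similarity ≥ 0.99.

**Missing-index grid.** Cell-type fractions {1/6, 1/3, 1/2, 2/3} ×
LR-gene fractions {1/10, 3/10, 1/2} × affected-sample fractions
{1/5, 2/5, 2/3}; in each affected sample the dropped cell types and
zeroed connected LR genes are drawn independently. Benchmark
decompositions reuse the gold standard's elbow-selected rank for every
perturbed run so that similarities are comparable, and perturbed tensors
are aligned to the gold tensor's element lists before decomposition.

Benchmark scoring runs with `n_perms = 0`: the tensor is built from the
magnitude consensus, which does not involve permutation p-values, so
skipping them changes nothing downstream while keeping the grid sweeps
fast. Problem sizes: the acceptance script runs the reference
2000 × 5000 configuration; the test suite runs the same benchmarks at
600 genes × 1500 cells.

## Known limitations

- The decomposition is a local optimizer; multi-restart mitigates but
  does not eliminate sensitivity for near-degenerate tensors.
- GSEA p-values are permutation-resolution-limited (≥ 1/(permutations
  of matching sign)).
- The footprint regression assumes an additive linear effect of pathway
  weights on loadings and shares the usual collinearity caveats (the
  fit refuses rank-deficient designs rather than silently regularizing).
- Loadings of elements kept via `allow_empty_slices` are not
  interpretable (see above).
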