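"""Per-sample ligand-receptor scoring and the consensus rank aggregate.

Scores communication between a sender cluster ``i`` expressing a ligand
and a receiver cluster ``j`` expressing its receptor.  Six scoring
functions from the literature are re-derived on a common set of cluster
summary statistics (mean, Tukey trimean, expression proportion, z-score
of cluster means, log2 fold change), each producing a *magnitude* (how
strongly expressed the interaction is) and/or a *specificity* (how
exclusive it is to this sender-receiver pair).  Per score family, a
consensus is obtained by robust rank aggregation with beta
order-statistic p-values.

All statistics operate on the library-size normalized, log1p-transformed
expression matrix.  Heteromeric complexes are summarized subunit-wise
(minimum by default) for every statistic, matching the subunit-wise
expression-proportion gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import beta as beta_dist
from scipy.stats import rankdata

from .resources import expand_complexes, pair_id

logger = logging.getLogger(__name__)

LOG2FC_EPS = 1e-9  # pseudocount inside each log2 to guard zero means

#: method name -> (magnitude column, specificity column, permutation-based)
METHODS: dict[str, tuple[str | None, str | None, bool]] = {
    "cellphonedb": ("cellphone_mean", "cellphone_pval", True),
    "geometric": ("geometric_mean", "geometric_pval", True),
    "cellchat": ("cellchat_prob", "cellchat_pval", True),
    "scsignalr": ("scsignalr_score", None, False),
    "natmi": ("natmi_product", "natmi_spec", False),
    "connectome": ("connectome_product", "connectome_zmean", False),
    "log2fc": (None, "logfc_mean", False),
}

DEFAULT_METHODS = ("cellphonedb", "cellchat", "scsignalr", "natmi", "connectome", "log2fc")


@dataclass
class MethodSpec:
    """Scoring parameters shared by all methods.

    kh
        Half-saturation constant of the hill-like communication
        probability (0.5 by default).
    n_perms
        Number of label permutations for specificity p-values; 0 disables
        the permutation columns.
    expr_prop
        Minimum fraction of cells in a cluster expressing every subunit
        for an interaction to be admitted (0.1 by default).
    min_cells
        Minimum cluster size; smaller clusters are dropped entirely.
    complex_agg
        How subunit statistics are combined into a complex statistic:
        ``"min"`` (limiting subunit, default) or ``"mean"``.
    """

    kh: float = 0.5
    n_perms: int = 100
    expr_prop: float = 0.1
    min_cells: int = 5
    seed: int = 0
    complex_agg: str = "min"
    methods: tuple[str, ...] = DEFAULT_METHODS
    return_all_lrs: bool = False

    def __post_init__(self) -> None:
        if self.n_perms < 0:
            raise ValueError("n_perms must be >= 0")
        if not 0.0 <= self.expr_prop <= 1.0:
            raise ValueError("expr_prop must be in [0, 1]")
        if self.complex_agg not in {"min", "mean"}:
            raise ValueError("complex_agg must be 'min' or 'mean'")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown scoring method(s): {sorted(unknown)}")


def trimean(values, axis=None):
    """Tukey's trimean (Q1 + 2*median + Q3) / 4 with linear interpolation."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("trimean of an empty vector is undefined")
    q1, q2, q3 = np.quantile(values, [0.25, 0.5, 0.75], axis=axis)
    return (q1 + 2.0 * q2 + q3) / 4.0


def qc_normalize(
    adata,
    min_genes: int = 200,
    min_cells_per_gene: int = 3,
    max_genes: int | None = None,
    mito_pct_max: float = 15.0,
    target_sum: float = 1e4,
    mito_prefix: str = "MT-",
):
    """Standard QC filtering and library-size normalization.

    Removes cells with fewer than ``min_genes`` detected genes, genes seen
    in fewer than ``min_cells_per_gene`` cells, cells whose mitochondrial
    fraction is at or above ``mito_pct_max`` percent, and (optionally)
    cells with at least ``max_genes`` detected genes.  Remaining counts
    are scaled per cell to ``target_sum`` and log1p-transformed; the raw
    counts are kept in ``.layers["counts"]``.

    Returns a new AnnData; the input is not modified.
    """
    import scanpy as sc

    X = adata.X
    data = X.data if sparse.issparse(X) else np.asarray(X)
    if not np.isfinite(data).all():
        raise ValueError("expression matrix contains non-finite values (nan or inf)")
    if (data < 0).sum() > 0:
        raise ValueError("expression matrix contains negative values; raw counts expected")

    adata = adata.copy()
    sc.pp.filter_cells(adata, min_genes=min_genes)
    sc.pp.filter_genes(adata, min_cells=min_cells_per_gene)
    adata.var["mt"] = adata.var_names.str.startswith(mito_prefix)
    if adata.var["mt"].any():
        sc.pp.calculate_qc_metrics(
            adata, qc_vars=["mt"], percent_top=None, log1p=False, inplace=True
        )
        adata = adata[adata.obs["pct_counts_mt"] < mito_pct_max].copy()
    if max_genes is not None:
        adata = adata[adata.obs["n_genes"] < max_genes].copy()
    if adata.n_obs == 0:
        raise ValueError("no cells left after QC filtering")
    adata.layers["counts"] = adata.X.copy()
    sc.pp.normalize_total(adata, target_sum=target_sum)
    sc.pp.log1p(adata)
    return adata


@dataclass
class ClusterSummary:
    """Per-cluster summary statistics on the normalized log matrix.

    All frames are genes x clusters; ``mu`` is the global mean of the full
    expression matrix (all genes, all cells of the sample).
    """

    mean: pd.DataFrame
    prop: pd.DataFrame
    trimean: pd.DataFrame
    z: pd.DataFrame
    log2fc: pd.DataFrame
    n_cells: pd.Series
    mu: float
    clusters: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.clusters:
            self.clusters = list(self.mean.columns)


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X, dtype=float)


def _cluster_means(M: np.ndarray, groups: np.ndarray, n_groups: int) -> np.ndarray:
    """Mean of M (genes x cells) per group of cells -> genes x n_groups."""
    ind = np.zeros((M.shape[1], n_groups))
    ind[np.arange(M.shape[1]), groups] = 1.0
    counts = ind.sum(axis=0)
    return (M @ ind) / np.maximum(counts, 1)


def summarize_clusters(
    M: np.ndarray,
    labels: np.ndarray,
    genes: pd.Index,
    mu: float | None = None,
    min_cells: int = 5,
) -> ClusterSummary:
    """Compute all cluster summary statistics on a genes x cells matrix.

    Clusters with fewer than ``min_cells`` cells are dropped.  The z-score
    of a gene is taken across the retained clusters' mean expression
    (constant genes get z = 0); log2 fold change contrasts the in-cluster
    mean with the mean over all other retained clusters' cells.
    """
    M = np.asarray(M, dtype=float)
    labels = np.asarray(labels)
    keep_names = [
        c for c in pd.unique(labels) if (labels == c).sum() >= min_cells
    ]
    if not keep_names:
        raise ValueError(
            f"no cluster has at least min_cells={min_cells} cells"
        )
    keep_names = sorted(map(str, keep_names))
    cell_keep = np.isin(labels.astype(str), keep_names)
    M_k = M[:, cell_keep]
    lab_k = labels.astype(str)[cell_keep]
    codes = pd.Categorical(lab_k, categories=keep_names).codes
    n_g = len(keep_names)

    mean = _cluster_means(M_k, codes, n_g)
    prop = _cluster_means((M_k > 0).astype(float), codes, n_g)
    tm = np.empty_like(mean)
    fc = np.empty_like(mean)
    for g in range(n_g):
        in_g = codes == g
        tm[:, g] = trimean(M_k[:, in_g], axis=1)
        out_mean = M_k[:, ~in_g].mean(axis=1) if (~in_g).any() else np.zeros(M.shape[0])
        fc[:, g] = np.log2(mean[:, g] + LOG2FC_EPS) - np.log2(out_mean + LOG2FC_EPS)

    sd = mean.std(axis=1, ddof=1) if n_g > 1 else np.zeros(mean.shape[0])
    center = mean.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd[:, None] > 0, (mean - center) / sd[:, None], 0.0)

    as_df = lambda a: pd.DataFrame(a, index=genes, columns=keep_names)
    return ClusterSummary(
        mean=as_df(mean),
        prop=as_df(prop),
        trimean=as_df(tm),
        z=as_df(z),
        log2fc=as_df(fc),
        n_cells=pd.Series(
            [(lab_k == c).sum() for c in keep_names], index=keep_names
        ),
        mu=float(M.mean()) if mu is None else float(mu),
        clusters=keep_names,
    )


def _complex_stat(stat: pd.DataFrame, subunit_lists: list[list[str]], agg: str) -> np.ndarray:
    """Summarize a genes x clusters statistic per complex -> complexes x clusters."""
    out = np.empty((len(subunit_lists), stat.shape[1]))
    values = stat.to_numpy()
    index = {g: i for i, g in enumerate(stat.index)}
    for k, subs in enumerate(subunit_lists):
        rows = values[[index[g] for g in subs]]
        out[k] = rows.min(axis=0) if agg == "min" else rows.mean(axis=0)
    return out


def filter_interactions(
    lig_prop: np.ndarray, rec_prop: np.ndarray, expr_prop: float
) -> np.ndarray:
    """Boolean admission grid (pairs x senders x receivers).

    A triple is admitted iff every ligand subunit reaches ``expr_prop``
    expression proportion in the sender and every receptor subunit does in
    the receiver (subunit-wise proportions are pre-aggregated by min).
    """
    return (lig_prop[:, :, None] >= expr_prop) & (rec_prop[:, None, :] >= expr_prop)


def _method_scores(
    L: np.ndarray,
    R: np.ndarray,
    TmL: np.ndarray,
    TmR: np.ndarray,
    kh: float,
    mu: float,
) -> dict[str, np.ndarray]:
    """Closed-form magnitude scores from summarized ligand/receptor expression."""
    prod = L * R
    geo = np.sqrt(prod)
    tmprod = TmL * TmR
    return {
        "cellphone_mean": (L + R) / 2.0,
        "geometric_mean": geo,
        "cellchat_prob": tmprod / (kh + tmprod),
        "scsignalr_score": geo / (geo + mu) if mu > 0 else np.zeros_like(geo),
        "natmi_product": prod,
        "connectome_product": prod,
    }


def score_sample(
    M: np.ndarray,
    labels: np.ndarray,
    genes: pd.Index,
    resource: pd.DataFrame,
    spec: MethodSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Score all admitted (LR pair, sender, receiver) triples for one sample.

    ``M`` is the normalized log expression (genes x cells).  Returns a long
    DataFrame; permutation p-value columns are present only if
    ``spec.n_perms >= 1``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    expanded = expand_complexes(resource)
    gene_set = set(genes)
    pairs, lig_subs, rec_subs, skipped = [], [], [], 0
    for pid, (ls, rs) in expanded.items():
        if all(g in gene_set for g in ls + rs):
            pairs.append(pid)
            lig_subs.append(ls)
            rec_subs.append(rs)
        else:
            skipped += 1
    if skipped:
        logger.warning("%d LR pairs skipped: subunit gene(s) absent from matrix", skipped)
    if not pairs:
        raise ValueError("no LR pair has all subunit genes in the expression matrix")

    mu = float(np.asarray(M, dtype=float).mean())
    used_genes = sorted({g for subs in lig_subs + rec_subs for g in subs})
    gi = pd.Index(genes)
    rows_idx = gi.get_indexer(used_genes)
    M_used = np.asarray(M, dtype=float)[rows_idx]
    summ = summarize_clusters(
        M_used, labels, pd.Index(used_genes), mu=mu, min_cells=spec.min_cells
    )
    clusters = summ.clusters
    n_c = len(clusters)
    agg = spec.complex_agg

    lig = {s: _complex_stat(getattr(summ, s), lig_subs, agg) for s in ("mean", "prop", "trimean", "z", "log2fc")}
    rec = {s: _complex_stat(getattr(summ, s), rec_subs, agg) for s in ("mean", "prop", "trimean", "z", "log2fc")}

    admitted = filter_interactions(lig["prop"], rec["prop"], spec.expr_prop)
    if spec.return_all_lrs:
        grid = np.ones_like(admitted, dtype=bool)
    else:
        grid = admitted
    p_idx, i_idx, j_idx = np.nonzero(grid)
    if p_idx.size == 0:
        return pd.DataFrame()

    L = lig["mean"][p_idx, i_idx]
    R = rec["mean"][p_idx, j_idx]
    TmL = lig["trimean"][p_idx, i_idx]
    TmR = rec["trimean"][p_idx, j_idx]
    scores = _method_scores(L, R, TmL, TmR, spec.kh, mu)

    # NATMI specificity: each side's expression as a fraction of its sum
    # over retained clusters (Eq-style fraction; zero-sum guarded).
    lsum = lig["mean"].sum(axis=1)
    rsum = rec["mean"].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfrac = np.where(lsum[p_idx] > 0, L / lsum[p_idx], 0.0)
        rfrac = np.where(rsum[p_idx] > 0, R / rsum[p_idx], 0.0)
    scores["natmi_spec"] = lfrac * rfrac
    scores["connectome_zmean"] = (lig["z"][p_idx, i_idx] + rec["z"][p_idx, j_idx]) / 2.0
    scores["logfc_mean"] = (lig["log2fc"][p_idx, i_idx] + rec["log2fc"][p_idx, j_idx]) / 2.0

    active_cols = set()
    for m in spec.methods:
        mag, specif, _ = METHODS[m]
        active_cols.update(c for c in (mag, specif) if c)

    out = pd.DataFrame(
        {
            "source": np.asarray(clusters)[i_idx],
            "target": np.asarray(clusters)[j_idx],
            "ligand_complex": np.asarray([p.split("^")[0] for p in pairs])[p_idx],
            "receptor_complex": np.asarray([p.split("^")[1] for p in pairs])[p_idx],
        }
    )
    for col, vals in scores.items():
        if col in active_cols:
            out[col] = vals

    perm_methods = [
        m for m in spec.methods if METHODS[m][2] and METHODS[m][1] in active_cols
    ]
    if spec.n_perms >= 1 and perm_methods:
        pvals = _permutation_pvalues(
            M_used, labels, clusters, lig_subs, rec_subs, p_idx, i_idx, j_idx,
            scores, perm_methods, spec, rng,
        )
        for m in perm_methods:
            out[METHODS[m][1]] = pvals[m]

    if spec.return_all_lrs:
        not_adm = ~admitted[p_idx, i_idx, j_idx]
        for m in spec.methods:
            mag, specif, _ = METHODS[m]
            if mag in out:
                out.loc[not_adm, mag] = 0.0
            if specif in out:
                out.loc[not_adm, specif] = 1.0
    return out


def _permutation_pvalues(
    M_used, labels, clusters, lig_subs, rec_subs, p_idx, i_idx, j_idx,
    scores, perm_methods, spec, rng,
):
    """Eq-style permutation p: fraction of label shuffles whose re-scored
    value is >= the observed one (ties count)."""
    labels = np.asarray(labels).astype(str)
    cell_keep = np.isin(labels, clusters)
    Mk = M_used[:, cell_keep]
    codes = np.asarray(pd.Categorical(labels[cell_keep], categories=clusters).codes)
    n_g = len(clusters)

    # subunit gene -> row of Mk (M_used rows follow the sorted used-gene order)
    used_genes = sorted({g for subs in lig_subs + rec_subs for g in subs})
    row_of = {g: i for i, g in enumerate(used_genes)}
    lig_rows = [[row_of[g] for g in subs] for subs in lig_subs]
    rec_rows = [[row_of[g] for g in subs] for subs in rec_subs]

    def complex_rows(stat, subs_rows):
        out = np.empty((len(subs_rows), stat.shape[1]))
        for k, rows in enumerate(subs_rows):
            block = stat[rows]
            out[k] = block.min(axis=0) if spec.complex_agg == "min" else block.mean(axis=0)
        return out

    counts = {m: np.zeros(p_idx.size) for m in perm_methods}
    need_tm = "cellchat" in perm_methods
    for _ in range(spec.n_perms):
        perm = rng.permutation(codes)
        mean_p = _cluster_means(Mk, perm, n_g)
        ligm = complex_rows(mean_p, lig_rows)
        recm = complex_rows(mean_p, rec_rows)
        Lp = ligm[p_idx, i_idx]
        Rp = recm[p_idx, j_idx]
        if "cellphonedb" in perm_methods:
            counts["cellphonedb"] += (Lp + Rp) / 2.0 >= scores["cellphone_mean"]
        if "geometric" in perm_methods:
            counts["geometric"] += np.sqrt(Lp * Rp) >= scores["geometric_mean"]
        if need_tm:
            tm_p = np.empty_like(mean_p)
            for g in range(n_g):
                sel = perm == g
                tm_p[:, g] = trimean(Mk[:, sel], axis=1) if sel.any() else 0.0
            ligt = complex_rows(tm_p, lig_rows)
            rect = complex_rows(tm_p, rec_rows)
            tp = ligt[p_idx, i_idx] * rect[p_idx, j_idx]
            counts["cellchat"] += tp / (spec.kh + tp) >= scores["cellchat_prob"]
    return {m: counts[m] / spec.n_perms for m in perm_methods}


def aggregate_ranks(
    score_matrix: np.ndarray,
    ascending: list[bool],
    bonferroni: str = "n",
) -> np.ndarray:
    """Robust rank aggregation of m score vectors over n interactions.

    Each column of the m x n ``score_matrix`` holds one method's scores;
    ``ascending[i]`` is True when smaller values are better (p-values).
    Ranks are normalized to (0, 1] (rank / max rank, average ties), the
    normalized ranks of each interaction are sorted, and the aggregate is
    the minimum over k of the beta order-statistic probability
    P(k-th smallest of m uniforms <= r_(k)), Bonferroni-multiplied by the
    number of interactions (``bonferroni="n"``, default) or by the number
    of score vectors (``"m"``), capped at 1.
    """
    S = np.asarray(score_matrix, dtype=float)
    if S.ndim != 2:
        raise ValueError("score_matrix must be 2D (m methods x n interactions)")
    m, n = S.shape
    if len(ascending) != m:
        raise ValueError("one direction flag per score vector is required")
    if bonferroni not in {"n", "m"}:
        raise ValueError("bonferroni must be 'n' or 'm'")
    R = np.empty_like(S)
    for i in range(m):
        vals = S[i] if ascending[i] else -S[i]
        r = rankdata(vals, method="average")
        R[i] = r / r.max()
    R.sort(axis=0)
    k = np.arange(1, m + 1)[:, None]
    probs = beta_dist.cdf(R, k, m - k + 1)
    rho = probs.min(axis=0)
    factor = n if bonferroni == "n" else m
    return np.minimum(1.0, rho * factor)


def add_rank_aggregates(table: pd.DataFrame, spec: MethodSpec) -> pd.DataFrame:
    """Append ``magnitude_rank`` and ``specificity_rank`` consensus columns.

    Magnitude columns rank descending (higher is stronger); specificity
    ranks ascending for p-value columns and descending for specificity
    weights / z-means / log2FC means.
    """
    mag_cols, spec_cols = [], []
    for mname in spec.methods:
        mag, specif, permuted = METHODS[mname]
        if mag and mag in table:
            mag_cols.append((mag, False))
        if specif and specif in table:
            spec_cols.append((specif, permuted))  # p-values ascend
    out = table.copy()
    for name, cols in (("magnitude_rank", mag_cols), ("specificity_rank", spec_cols)):
        if not cols:
            continue
        S = np.stack([table[c].to_numpy(float) for c, _ in cols])
        out[name] = aggregate_ranks(S, [asc for _, asc in cols])
    return out


def score_by_sample(
    adata,
    resource: pd.DataFrame,
    sample_key: str,
    groupby: str,
    spec: MethodSpec | None = None,
) -> pd.DataFrame:
    """Run the full scoring pipeline independently on every sample.

    ``adata.X`` must hold the normalized log expression (cells x genes, the
    AnnData convention); ``adata.obs[sample_key]`` and
    ``adata.obs[groupby]`` give the sample and cell-type labels.  Returns
    the concatenated ScoreTable with per-sample consensus rank columns.
    """
    if spec is None:
        spec = MethodSpec()
    for col in (sample_key, groupby):
        if col not in adata.obs:
            raise KeyError(f"adata.obs is missing required column {col!r}")
    blocks = []
    for sample in pd.unique(adata.obs[sample_key]):
        sub = adata[adata.obs[sample_key] == sample]
        M = _dense(sub.X).T  # genes x cells
        try:
            # the permutation stream restarts per sample, so identical
            # samples yield identical score blocks
            tbl = score_sample(
                M,
                sub.obs[groupby].to_numpy(),
                sub.var_names,
                resource,
                spec,
                rng=np.random.default_rng(spec.seed),
            )
        except ValueError as err:
            logger.warning("sample %s skipped: %s", sample, err)
            continue
        if tbl.empty:
            logger.warning("sample %s has no admitted interactions; omitted", sample)
            continue
        tbl = add_rank_aggregates(tbl, spec)
        tbl.insert(0, "sample", sample)
        blocks.append(tbl)
    if not blocks:
        raise ValueError("no sample produced any admitted interactions")
    return pd.concat(blocks, ignore_index=True)
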