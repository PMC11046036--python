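"""Factor interpretation: preranked GSEA on LR sets and footprint regression.

Given the LR-pair loadings of each decomposition factor, two
complementary enrichment routes are offered:

* **Preranked GSEA** on unweighted pathway LR sets — a weighted
  Kolmogorov-Smirnov running-sum statistic with a permutation null,
  normalized enrichment scores (NES), and BH-adjusted p-values.
* **Footprint regression** on signed, weighted pathway LR sets — one
  ordinary least-squares fit per factor of the loading vector on all
  pathway weight columns jointly (plus intercept); each pathway's
  t-value and two-sided p-value measure its association with the factor.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def enrichment_score(
    ranked_ids: list[str],
    ranked_values: np.ndarray,
    member: np.ndarray,
    weight: float = 1.0,
) -> float:
    """Weighted KS enrichment score of a member set in a ranked list.

    ``ranked_ids``/``ranked_values`` are sorted best-first (descending
    loading); ``member`` is a boolean hit vector aligned with them.  Hits
    advance the running sum by |value|^weight (normalized over hits),
    misses retreat it by 1/(N - Nh); the ES is the extremum of the
    running sum (sign kept).
    """
    member = np.asarray(member, dtype=bool)
    values = np.asarray(ranked_values, dtype=float)
    n = len(values)
    nh = int(member.sum())
    if nh == 0 or nh == n:
        raise ValueError("member set must be a proper non-empty subset of the ranking")
    w = np.abs(values) ** weight
    hit_sum = w[member].sum()
    step = np.where(member, (w / hit_sum) if hit_sum > 0 else (member / nh), -1.0 / (n - nh))
    if hit_sum == 0:  # all-zero loadings under weight > 0: flat hit steps
        step = np.where(member, 1.0 / nh, -1.0 / (n - nh))
    running = np.cumsum(step)
    return float(running[np.argmax(np.abs(running))])


def gsea_prerank(
    loadings: pd.DataFrame,
    lr_sets: dict[str, set[str]],
    weight: float = 1.0,
    min_size: int = 15,
    permutations: int = 999,
    seed: int = 0,
    significance_threshold: float = 0.05,
) -> pd.DataFrame:
    """Preranked GSEA of pathway LR sets against per-factor loadings.

    ``loadings`` is LR pairs x factors (non-negative).  Sets smaller than
    ``min_size`` (intersected with the ranked universe) are skipped.  The
    null distribution per (factor, pathway) comes from ``permutations``
    random hit placements; NES divides the ES by the mean |null ES| of
    matching sign and the p-value is the matching-sign null tail
    (ties included, observed excluded from the null).  P-values are
    BH-adjusted across all (factor, pathway) tests.
    """
    rng = np.random.default_rng(seed)
    universe = list(loadings.index)
    rows, skipped = [], []
    for pw, members in lr_sets.items():
        hits = [p for p in universe if p in members]
        if len(hits) < min_size or len(hits) == len(universe):
            skipped.append(pw)
            continue
        for factor in loadings.columns:
            vals = loadings[factor].to_numpy(float)
            order = np.argsort(-vals, kind="stable")
            ranked_ids = [universe[i] for i in order]
            ranked_vals = vals[order]
            member = np.isin(ranked_ids, hits)
            es = enrichment_score(ranked_ids, ranked_vals, member, weight)
            nh = member.sum()
            null = np.empty(permutations)
            for b in range(permutations):
                perm = np.zeros(len(universe), dtype=bool)
                perm[rng.choice(len(universe), size=nh, replace=False)] = True
                null[b] = enrichment_score(ranked_ids, ranked_vals, perm, weight)
            same = null >= 0 if es >= 0 else null < 0
            n_same = int(same.sum())
            denom = np.abs(null[same]).mean() if n_same else np.nan
            nes = es / denom if n_same and denom > 0 else np.nan
            if n_same:
                p = (np.abs(null[same]) >= abs(es)).sum() / n_same
            else:
                p = 1.0 / (permutations + 1)
            rows.append((factor, pw, es, nes, float(p)))
    if skipped:
        logger.info("%d set(s) below min_size=%d skipped", len(skipped), min_size)
    out = pd.DataFrame(rows, columns=["factor", "pathway", "es", "nes", "pvalue"])
    if len(out):
        out["padj"] = multipletests(out["pvalue"], method="fdr_bh")[1]
        out["significant"] = out["padj"] < significance_threshold
    out.attrs["skipped_sets"] = skipped
    return out


def footprint_mlm(
    loadings: pd.DataFrame,
    weighted_lr_sets: pd.DataFrame,
    standardize_response: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multivariate linear footprint enrichment of weighted LR sets.

    ``weighted_lr_sets`` is long format (``source`` pathway,
    ``interaction`` LR pair, ``weight``).  Per factor, the loading vector
    over all LR pairs is regressed jointly on the pathway weight columns
    (zeros for non-members) with an intercept.  Returns ``(t_values,
    p_values)`` frames shaped factors x pathways.
    """
    X = weighted_lr_sets.pivot_table(
        index="interaction", columns="source", values="weight", fill_value=0.0
    )
    X = X.reindex(loadings.index, fill_value=0.0)
    empty = X.columns[(X == 0).all(axis=0)]
    if len(empty):
        logger.warning("pathway column(s) with no member in the loading universe dropped: %s", list(empty))
        X = X.drop(columns=empty)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 pathways with members among the LR pairs")
    design = sm.add_constant(X.to_numpy(float))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            f"rank-deficient design: collinear pathway columns among {list(X.columns)}"
        )
    t_rows, p_rows = [], []
    for factor in loadings.columns:
        y = loadings[factor].to_numpy(float)
        if standardize_response:
            sd = y.std(ddof=1)
            y = (y - y.mean()) / sd if sd > 0 else y - y.mean()
        fit = sm.OLS(y, design).fit()
        t_rows.append(fit.tvalues[1:])
        p_rows.append(fit.pvalues[1:])
    t = pd.DataFrame(t_rows, index=loadings.columns, columns=X.columns)
    p = pd.DataFrame(p_rows, index=loadings.columns, columns=X.columns)
    return t, p
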