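"""4D communication tensors and their non-negative CP decomposition.

The tensor is indexed (context, LR pair, sender cell type, receiver cell
type) and holds communication scores; entries absent from the score
table (an interaction not admitted in some context) can be treated as
missing (excluded from the decomposition objective) or as literal zeros.
A rank-R non-negative canonical polyadic (CP) model expresses the tensor
as a sum of R rank-one "communication programs", each described by one
non-negative loading vector per mode.

The decomposition is fitted by hierarchical alternating least squares
(HALS) with EM-style handling of missing entries: before each sweep,
missing cells are imputed with the current model reconstruction, so the
objective only penalizes misfit on observed entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MODE_NAMES = ("Contexts", "Ligand-Receptor Pairs", "Sender Cells", "Receiver Cells")


@dataclass
class CommunicationTensor:
    """4D score array with a missing-entry mask and per-mode element names."""

    data: np.ndarray  # contexts x lr_pairs x senders x receivers
    missing: np.ndarray  # bool, True where the entry is missing
    contexts: list[str]
    lr_pairs: list[str]
    senders: list[str]
    receivers: list[str]
    groups: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.data.shape != self.missing.shape:
            raise ValueError("data and missing mask shapes differ")
        expect = (len(self.contexts), len(self.lr_pairs), len(self.senders), len(self.receivers))
        if self.data.shape != expect:
            raise ValueError(f"tensor shape {self.data.shape} != element lists {expect}")
        for name, els in zip(MODE_NAMES, self.mode_elements):
            if len(set(els)) != len(els):
                raise ValueError(f"duplicate elements in mode {name}")
        obs = self.data[~self.missing]
        if obs.size and not np.isfinite(obs).all():
            raise ValueError("tensor has non-finite observed entries")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def mode_elements(self) -> tuple[list[str], ...]:
        return (self.contexts, self.lr_pairs, self.senders, self.receivers)

    def to_long(self) -> pd.DataFrame:
        """Observed entries in long format (round-trips ``build_tensor``)."""
        idx = np.argwhere(~self.missing)
        return pd.DataFrame(
            {
                "context": [self.contexts[i] for i in idx[:, 0]],
                "lr_pair": [self.lr_pairs[i] for i in idx[:, 1]],
                "sender": [self.senders[i] for i in idx[:, 2]],
                "receiver": [self.receivers[i] for i in idx[:, 3]],
                "value": self.data[tuple(idx.T)],
            }
        )

    def save(self, path) -> None:
        """Serialize to a single ``.npz`` container (data, mask, mode names)."""
        np.savez_compressed(
            path,
            data=self.data,
            missing=self.missing,
            contexts=np.array(self.contexts, dtype=object),
            lr_pairs=np.array(self.lr_pairs, dtype=object),
            senders=np.array(self.senders, dtype=object),
            receivers=np.array(self.receivers, dtype=object),
        )

    @classmethod
    def load(cls, path) -> "CommunicationTensor":
        z = np.load(path, allow_pickle=True)
        return cls(
            data=z["data"],
            missing=z["missing"],
            contexts=list(z["contexts"]),
            lr_pairs=list(z["lr_pairs"]),
            senders=list(z["senders"]),
            receivers=list(z["receivers"]),
        )


def _elements(present: pd.DataFrame, col: str, how_union: bool, n_contexts: int, outer_fraction: float):
    per_ctx = present.groupby(col)["context"].nunique()
    if not how_union:
        return sorted(per_ctx[per_ctx == n_contexts].index)
    if outer_fraction <= 0:
        return sorted(per_ctx.index)
    return sorted(per_ctx[per_ctx >= outer_fraction * n_contexts].index)


def build_tensor(
    table: pd.DataFrame,
    score_column: str = "magnitude_rank",
    inverse_fun=lambda x: 1.0 - x,
    how: str = "outer",
    outer_fraction: float = 0.0,
    fill_missing: str = "mask",
    context_order: list[str] | None = None,
    sample_key: str = "sample",
    source_key: str = "source",
    target_key: str = "target",
    ligand_key: str = "ligand_complex",
    receptor_key: str = "receptor_complex",
    lr_fill=None,
    cell_fill=None,
) -> CommunicationTensor:
    """Assemble the 4D communication tensor from a long score table.

    ``how`` selects which LR pairs and cell types enter the tensor:
    ``"inner"`` keeps only elements present in every context,
    ``"outer"`` the union across contexts, ``"outer_lrs"`` /
    ``"outer_cells"`` mix the two.  For union modes, ``outer_fraction``
    keeps an element only if it appears in at least that fraction of
    contexts (1.0 behaves like ``"inner"``).  Scores are transformed by
    ``inverse_fun`` (default ``1 - x``, turning best-first rank scores
    into higher-is-stronger values).  Entries absent from the table are
    masked as missing (``fill_missing="mask"``) or set to 0 (``"zero"``).

    ``lr_fill`` / ``cell_fill`` optionally force explicit element lists
    (e.g. to align a perturbed tensor with a reference tensor's modes).
    """
    if how not in {"inner", "outer", "outer_lrs", "outer_cells"}:
        raise ValueError(f"unknown how: {how!r}")
    if fill_missing not in {"mask", "zero"}:
        raise ValueError("fill_missing must be 'mask' or 'zero'")
    df = table[[sample_key, source_key, target_key, ligand_key, receptor_key, score_column]].copy()
    df.columns = ["context", "source", "target", "ligand", "receptor", "score"]
    df["lr_pair"] = df["ligand"].astype(str) + "^" + df["receptor"].astype(str)
    contexts = list(context_order) if context_order is not None else sorted(df["context"].unique())
    if set(df["context"]) - set(contexts):
        raise ValueError("context_order does not cover all contexts in the table")
    n_ctx = len(contexts)

    lr_union = how in {"outer", "outer_lrs"}
    cell_union = how in {"outer", "outer_cells"}
    if lr_fill is not None:
        lr_pairs = list(lr_fill)
    else:
        lr_pairs = _elements(df, "lr_pair", lr_union, n_ctx, outer_fraction)
    if cell_fill is not None:
        cells = list(cell_fill)
    else:
        cell_long = pd.concat(
            [
                df[["context", "source"]].rename(columns={"source": "cell"}),
                df[["context", "target"]].rename(columns={"target": "cell"}),
            ]
        )
        cells = _elements(cell_long, "cell", cell_union, n_ctx, outer_fraction)
    if not lr_pairs or not cells:
        raise ValueError(
            "empty tensor mode after the how/outer_fraction policy; "
            "re-score with a smaller expr_prop or rebuild with a larger "
            "outer_fraction / how='outer'"
        )

    shape = (n_ctx, len(lr_pairs), len(cells), len(cells))
    data = np.zeros(shape)
    missing = np.ones(shape, dtype=bool)
    ctx_i = {c: i for i, c in enumerate(contexts)}
    lr_i = {p: i for i, p in enumerate(lr_pairs)}
    cell_i = {c: i for i, c in enumerate(cells)}

    sub = df[
        df["lr_pair"].isin(lr_i) & df["source"].isin(cell_i) & df["target"].isin(cell_i)
    ]
    vals = sub["score"].to_numpy(float)
    if inverse_fun is not None:
        vals = inverse_fun(vals)
    idx = (
        sub["context"].map(ctx_i).to_numpy(),
        sub["lr_pair"].map(lr_i).to_numpy(),
        sub["source"].map(cell_i).to_numpy(),
        sub["target"].map(cell_i).to_numpy(),
    )
    data[idx] = vals
    missing[idx] = False
    if fill_missing == "zero":
        missing[:] = False
    return CommunicationTensor(
        data=data,
        missing=missing,
        contexts=contexts,
        lr_pairs=list(lr_pairs),
        senders=list(cells),
        receivers=list(cells),
    )


@dataclass
class DecompositionResult:
    """Rank-R non-negative CP fit: unit-norm factors, weights, fit error."""

    rank: int
    factors: list[np.ndarray]  # one (mode_dim x rank) matrix per mode
    weights: np.ndarray  # per-component scale absorbed from the factors
    rel_error: float
    n_iter: int
    converged: bool
    seed: int | None = None
    mode_names: tuple[str, ...] = MODE_NAMES
    mode_elements: tuple[list[str], ...] | None = None

    def factor_frames(self) -> dict[str, pd.DataFrame]:
        """Loadings per mode as DataFrames (element x Factor columns)."""
        cols = [f"Factor {r + 1}" for r in range(self.rank)]
        out = {}
        for name, F, els in zip(
            self.mode_names,
            self.factors,
            self.mode_elements or [None] * len(self.factors),
        ):
            out[name] = pd.DataFrame(F, columns=cols, index=els)
        return out

    def reconstruct(self) -> np.ndarray:
        return _cp_to_tensor(self.factors, self.weights)


def _khatri_rao(mats: list[np.ndarray]) -> np.ndarray:
    out = mats[0]
    for M in mats[1:]:
        out = (out[:, None, :] * M[None, :, :]).reshape(-1, M.shape[1])
    return out


def _cp_to_tensor(factors: list[np.ndarray], weights: np.ndarray | None = None) -> np.ndarray:
    R = factors[0].shape[1]
    w = np.ones(R) if weights is None else weights
    kr = _khatri_rao(factors[1:])
    M0 = (factors[0] * w) @ kr.T
    return M0.reshape([F.shape[0] for F in factors])


def _unfold(T: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(T, mode, 0).reshape(T.shape[mode], -1)


def _init_factors(T: np.ndarray, rank: int, init: str, rng: np.random.Generator) -> list[np.ndarray]:
    factors = []
    for mode in range(T.ndim):
        dim = T.shape[mode]
        if init == "svd" and rank <= min(_unfold(T, mode).shape):
            U, s, _ = np.linalg.svd(_unfold(T, mode), full_matrices=False)
            F = np.abs(U[:, :rank] * s[:rank])
        else:
            F = rng.random((dim, rank))
        F = np.maximum(F, 1e-12)
        factors.append(F)
    return factors


def nncp_decompose(
    tensor: CommunicationTensor | np.ndarray,
    rank: int,
    init: str = "svd",
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 100,
    robust: bool = False,
    n_restarts: int = 1,
    allow_empty_slices: bool = False,
) -> DecompositionResult:
    """Fit a rank-R non-negative CP model by masked HALS.

    Missing entries are excluded from the objective by imputing them with
    the running reconstruction before each sweep (EM flavour).  The
    reported ``rel_error`` is ||observed - model|| / ||observed|| over
    unmasked entries only.  ``robust=True`` tightens the tolerance to
    1e-8 and allows 500 iterations.  ``n_restarts > 1`` refits from
    consecutive seeds and keeps the lowest-error solution (ALS can land
    in local minima).
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if n_restarts > 1:
        fits = [
            nncp_decompose(
                tensor, rank, init=init, seed=seed + k, tol=tol,
                max_iter=max_iter, robust=robust, n_restarts=1,
                allow_empty_slices=allow_empty_slices,
            )
            for k in range(n_restarts)
        ]
        return min(fits, key=lambda r: r.rel_error)
    if robust:
        tol, max_iter = min(tol, 1e-8), max(max_iter, 500)
    if isinstance(tensor, CommunicationTensor):
        X, miss, mode_elements = tensor.data, tensor.missing, tensor.mode_elements
    else:
        X = np.asarray(tensor, dtype=float)
        miss = ~np.isfinite(X)
        mode_elements = None
    if not np.isfinite(X[~miss]).all():
        raise ValueError("tensor has non-finite observed entries")
    if (X[~miss] < 0).any():
        raise ValueError(
            "tensor has negative observed entries; transform communication "
            "scores to a non-negative scale before decomposing"
        )
    obs = ~miss
    for mode in range(X.ndim):
        per_slice = obs.sum(axis=tuple(d for d in range(X.ndim) if d != mode))
        if (per_slice == 0).any() and not allow_empty_slices:
            raise ValueError(
                f"mode {mode} has a slice with no observed entries; pass "
                "allow_empty_slices=True to keep such elements (their "
                "loadings are determined only by the bounded imputation)"
            )

    rng = np.random.default_rng(seed)
    Xw = np.where(miss, 0.0, X)
    factors = _init_factors(Xw, rank, init, rng)
    norm_obs = np.linalg.norm(X[obs])
    if norm_obs == 0:
        raise ValueError("all observed entries are zero; nothing to decompose")

    prev_err = np.inf
    err = np.inf
    n_modes = X.ndim
    converged = False
    # EM imputations are clipped to the observed value range: communication
    # scores are bounded, and unclipped imputation lets components supported
    # mostly on masked blocks grow without penalty
    lo, hi = float(X[obs].min()), float(X[obs].max())
    for it in range(1, max_iter + 1):
        recon = _cp_to_tensor(factors)
        Xf = np.where(miss, np.clip(recon, lo, hi), X)
        for mode in range(n_modes):
            others = [factors[k] for k in range(n_modes) if k != mode]
            kr = _khatri_rao(others)
            G = np.ones((rank, rank))
            for F in others:
                G *= F.T @ F
            M = _unfold(Xf, mode) @ kr  # MTTKRP
            A = factors[mode]
            for r in range(rank):
                denom = G[r, r]
                if denom <= 1e-15:
                    A[:, r] = rng.random(A.shape[0]) * 1e-6
                    continue
                update = (M[:, r] - A @ G[:, r] + A[:, r] * denom) / denom
                A[:, r] = np.maximum(update, 0.0)
            if (A.sum(axis=0) == 0).any():
                dead = A.sum(axis=0) == 0
                A[:, dead] = rng.random((A.shape[0], dead.sum())) * 1e-6
            factors[mode] = A
        recon = _cp_to_tensor(factors)
        err = np.linalg.norm((X - recon)[obs]) / norm_obs
        if abs(prev_err - err) < tol:
            converged = True
            break
        prev_err = err

    # absorb scales: unit-norm columns, per-component weight
    weights = np.ones(rank)
    for mode in range(n_modes):
        norms = np.linalg.norm(factors[mode], axis=0)
        norms = np.where(norms > 0, norms, 1.0)
        factors[mode] = factors[mode] / norms
        weights *= norms
    order = np.argsort(weights)[::-1]
    factors = [F[:, order] for F in factors]
    weights = weights[order]
    return DecompositionResult(
        rank=rank,
        factors=factors,
        weights=weights,
        rel_error=float(err),
        n_iter=it,
        converged=converged,
        seed=seed,
        mode_elements=mode_elements,
    )


def select_rank_elbow(
    tensor: CommunicationTensor,
    max_rank: int = 10,
    runs: int = 3,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[int, pd.DataFrame]:
    """Reconstruction-error curve over ranks 1..max_rank with elbow pick.

    For each rank the decomposition is repeated ``runs`` times from
    different seeds and the mean relative error recorded.  The suggested
    rank maximizes the perpendicular distance to the chord joining the
    curve's endpoints (both axes scaled to [0, 1] first).
    """
    if max_rank < 2:
        raise ValueError("max_rank must be >= 2")
    rng = np.random.default_rng(seed)
    ranks = np.arange(1, max_rank + 1)
    errors = np.empty((len(ranks), runs))
    for a, rank in enumerate(ranks):
        for b in range(runs):
            res = nncp_decompose(
                tensor, rank=int(rank), seed=int(rng.integers(2**31 - 1)), **fit_kwargs
            )
            errors[a, b] = res.rel_error
    mean_err = errors.mean(axis=1)
    if mean_err[-1] > mean_err[0]:
        logger.warning(
            "error curve increases with rank; the tensor may be too sparse "
            "(consider a smaller expr_prop or a larger outer_fraction)"
        )
    x = (ranks - ranks[0]) / max(ranks[-1] - ranks[0], 1)
    span = mean_err[0] - mean_err[-1]
    y = (mean_err - mean_err[-1]) / span if abs(span) > 0 else np.zeros_like(mean_err)
    # distance from (x, y) to the chord joining (0, y0) and (1, y_last)
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    dist = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0) / np.hypot(y1 - y0, x1 - x0)
    suggested = int(ranks[np.argmax(dist)])
    curve = pd.DataFrame({"rank": ranks, "mean_rel_error": mean_err})
    return suggested, curve


def corrindex_similarity(a: DecompositionResult, b: DecompositionResult) -> float:
    """Similarity (1 - CorrIndex) between two CP decompositions.

    Factor matrices are stacked across modes, columns L2-normalized, and
    the CorrIndex computed from the absolute cross-product matrix; the
    measure is invariant to component permutation and positive rescaling
    and lies in [0, 1] (1 = same decomposition).
    """
    if a.rank != b.rank:
        raise ValueError("decompositions have different ranks")
    if [F.shape[0] for F in a.factors] != [F.shape[0] for F in b.factors]:
        raise ValueError("decompositions have different mode dimensions")
    A = np.vstack(a.factors)
    B = np.vstack(b.factors)
    A = A / np.maximum(np.linalg.norm(A, axis=0), 1e-300)
    B = B / np.maximum(np.linalg.norm(B, axis=0), 1e-300)
    C = np.abs(A.T @ B)
    R = a.rank
    corrindex = ((1 - C.max(axis=1)).sum() + (1 - C.max(axis=0)).sum()) / (2 * R)
    return float(1.0 - corrindex)


def factor_group_test(
    context_loadings: pd.DataFrame,
    groups: pd.Series | dict,
    correction: str = "fdr_bh",
) -> pd.DataFrame:
    """Pairwise independent t-tests of context loadings between groups.

    For every factor (column of ``context_loadings``) and every pair of
    groups with at least two contexts each, a two-sided independent
    t-test is run; p-values are adjusted across all tests (BH by
    default).  Significance tiers: ``ns``, ``*`` (p < 0.05), ``**``
    (p < 0.01) on the adjusted p.
    """
    groups = pd.Series(groups)
    groups = groups.reindex(context_loadings.index)
    if groups.isna().any():
        raise ValueError("every context needs a group label")
    rows = []
    for g1, g2 in combinations(sorted(groups.unique()), 2):
        idx1, idx2 = groups[groups == g1].index, groups[groups == g2].index
        if len(idx1) < 2 or len(idx2) < 2:
            logger.warning("group pair (%s, %s) skipped: fewer than 2 contexts", g1, g2)
            continue
        for factor in context_loadings.columns:
            stat, p = ttest_ind(
                context_loadings.loc[idx1, factor],
                context_loadings.loc[idx2, factor],
            )
            if not np.isfinite(p):  # zero variance in both groups
                stat, p = 0.0, 1.0
            rows.append((factor, g1, g2, float(stat), float(p)))
    if not rows:
        raise ValueError("no group pair had two or more contexts per group")
    out = pd.DataFrame(rows, columns=["factor", "group1", "group2", "statistic", "pvalue"])
    out["padj"] = multipletests(out["pvalue"], method=correction)[1]
    out["significance"] = np.select(
        [out["padj"] < 0.01, out["padj"] < 0.05], ["**", "*"], default="ns"
    )
    return out


def factor_networks(
    sender_loadings: pd.DataFrame,
    receiver_loadings: pd.DataFrame,
    threshold: float = 0.075,
    factors: list[str] | None = None,
) -> pd.DataFrame:
    """Factor-specific sender→receiver edges from loading outer products.

    Edge weight is sender loading x receiver loading; edges below
    ``threshold`` are dropped (0.075 is a practical default for unit-norm
    loadings).
    """
    if (sender_loadings.to_numpy() < 0).any() or (receiver_loadings.to_numpy() < 0).any():
        raise ValueError("loadings must be non-negative")
    use = factors if factors is not None else list(sender_loadings.columns)
    rows = []
    for f in use:
        w = np.outer(sender_loadings[f].to_numpy(), receiver_loadings[f].to_numpy())
        keep = np.argwhere(w >= threshold)
        for i, j in keep:
            rows.append((f, sender_loadings.index[i], receiver_loadings.index[j], w[i, j]))
    return pd.DataFrame(rows, columns=["factor", "sender", "receiver", "weight"])
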