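"""Readers, writers, and the run configuration.

Supported expression inputs: MTX triplet + TSV annotations, an h5ad
single-cell container (read-only), or a dense delimited matrix.  All
table outputs are comma-separated UTF-8 with a header row and no index
column.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from .resources import SchemaError

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Single-document JSON configuration for a pipeline run.

    Unknown keys are rejected so typos fail loudly; every stage derives
    its randomness deterministically from the top-level ``seed``.
    """

    model_config = ConfigDict(extra="forbid")

    expression_path: str | None = None
    expression_format: str = "auto"  # auto | mtx | h5ad | tsv
    metadata_path: str | None = None
    sample_key: str = "sample"
    groupby: str = "cell_type"
    resource: str = "consensus"
    methods: list[str] = ["cellphonedb", "cellchat", "scsignalr", "natmi", "connectome", "log2fc"]
    expr_prop: float = 0.1
    min_cells: int = 5
    n_perms: int = 100
    kh: float = 0.5
    complex_agg: str = "min"
    # QC / normalization
    min_genes: int = 200
    min_cells_per_gene: int = 3
    mito_pct_max: float = 15.0
    target_sum: float = 1e4
    # tensor / decomposition
    score_column: str = "magnitude_rank"
    how: str = "outer"
    outer_fraction: float = 0.0
    fill_missing: str = "mask"
    rank: int | None = None
    max_rank: int = 10
    tf_optimization: str = "regular"  # regular | robust
    # misc
    seed: int = 0
    output_dir: str = "cellcomm_out"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))


def _check_matrix(X) -> None:
    from scipy import sparse

    data = X.data if sparse.issparse(X) else np.asarray(X)
    if not np.isfinite(data).all():
        raise ValueError("expression matrix contains non-finite values (nan or inf)")
    if (data < 0).sum() > 0:
        raise ValueError(
            "expression matrix contains negative values; provide raw or "
            "library-size normalized counts (avoid centered or "
            "batch-corrected values)"
        )


def read_expression(
    path: str | Path,
    fmt: str = "auto",
    metadata_path: str | Path | None = None,
    sample_key: str = "sample",
    groupby: str = "cell_type",
):
    """Load a genes x cells expression matrix with per-cell metadata.

    Returns an AnnData (cells x genes, the single-cell convention) whose
    ``.obs`` carries the sample and cell-type columns.  For MTX input,
    ``path`` is the ``.mtx`` file and ``<stem>_genes.tsv`` /
    ``<stem>_barcodes.tsv`` are expected alongside unless a metadata
    table supplies everything.
    """
    import anndata as ad
    from scipy import io as spio, sparse

    path = Path(path)
    if fmt == "auto":
        fmt = {"mtx": "mtx", "h5ad": "h5ad"}.get(path.suffix.lstrip("."), "tsv")
    if fmt == "h5ad":
        adata = ad.read_h5ad(path)
    elif fmt == "mtx":
        M = sparse.csr_matrix(spio.mmread(path))  # genes x cells
        genes = pd.read_csv(path.with_name(path.stem + "_genes.tsv"), sep="\t", header=None)[0]
        cells = pd.read_csv(path.with_name(path.stem + "_barcodes.tsv"), sep="\t", header=None)[0]
        adata = ad.AnnData(
            X=M.T.tocsr(),
            obs=pd.DataFrame(index=pd.Index(cells.astype(str), name="cell")),
            var=pd.DataFrame(index=pd.Index(genes.astype(str), name="gene")),
        )
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)  # genes x cells
        adata = ad.AnnData(
            X=df.to_numpy(float).T,
            obs=pd.DataFrame(index=pd.Index(df.columns.astype(str), name="cell")),
            var=pd.DataFrame(index=pd.Index(df.index.astype(str), name="gene")),
        )
    else:
        raise ValueError(f"unsupported expression format: {fmt!r}")
    _check_matrix(adata.X)

    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep=None, engine="python", index_col=0)
        meta.index = meta.index.astype(str)
        adata.obs = adata.obs.join(meta, how="left")
    for col in (sample_key, groupby):
        if col not in adata.obs:
            raise SchemaError(f"cell metadata is missing required column {col!r}")
        if adata.obs[col].isna().any():
            raise ValueError(f"metadata column {col!r} has missing values")
    return adata


def write_mtx(dataset, out_dir: str | Path, prefix: str = "sim") -> None:
    """Write a simulated dataset as MTX + TSV annotations."""
    from scipy import io as spio, sparse

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / f"{prefix}.mtx", sparse.coo_matrix(dataset.counts))
    pd.Series(dataset.genes).to_csv(out / f"{prefix}_genes.tsv", sep="\t", index=False, header=False)
    pd.Series(dataset.obs.index).to_csv(out / f"{prefix}_barcodes.tsv", sep="\t", index=False, header=False)
    dataset.obs.to_csv(out / f"{prefix}_metadata.csv")


def write_outputs(results: dict, out_dir: str | Path) -> list[Path]:
    """Write pipeline artifacts with deterministic naming and column order.

    ``results`` may hold any of: ``score_table`` (DataFrame),
    ``tensor`` (CommunicationTensor), ``decomposition``
    (DecompositionResult), ``group_stats``, ``networks``, ``gsea``,
    ``footprint_t``/``footprint_p``, ``benchmark`` (DataFrames), and
    ``config`` (RunConfig).  Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_csv(df: pd.DataFrame, name: str, index: bool = False):
        p = out / name
        df.to_csv(p, index=index)
        written.append(p)

    if "score_table" in results:
        save_csv(results["score_table"], "score_table.csv")
    if "tensor" in results:
        p = out / "tensor.npz"
        results["tensor"].save(p)
        written.append(p)
    if "decomposition" in results:
        for mode, frame in results["decomposition"].factor_frames().items():
            slug = mode.lower().replace(" ", "_").replace("-", "_")
            save_csv(frame, f"loadings_{slug}.csv", index=True)
    if "group_stats" in results:
        save_csv(results["group_stats"], "factor_group_stats.csv")
    if "networks" in results:
        save_csv(results["networks"], "factor_networks.csv")
    if "gsea" in results:
        save_csv(results["gsea"], "gsea.csv")
    if "footprint_t" in results:
        save_csv(results["footprint_t"], "footprint_tvalues.csv", index=True)
    if "footprint_p" in results:
        save_csv(results["footprint_p"], "footprint_pvalues.csv", index=True)
    if "benchmark" in results:
        save_csv(results["benchmark"], "benchmark.csv")
    if "config" in results:
        p = out / "run_config.json"
        results["config"].to_json(p)
        written.append(p)
    return written
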