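"""Ligand-receptor prior-knowledge resources and pathway-level LR sets.

A resource is a two-column table of ligand and receptor identifiers.
Heteromeric complexes are encoded by joining subunit gene symbols with
``"_"`` (e.g. ``"IL6R_IL6ST"``); a ligand-receptor pair identifier joins
the two sides with ``"^"`` (e.g. ``"IL6^IL6R_IL6ST"``).  Gene identifiers
are treated as case-sensitive exact strings throughout: the resource and
the expression matrix must use the same symbol space.
"""

from __future__ import annotations

import logging
from importlib import resources as _ilr
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

COMPLEX_SEP = "_"
LR_SEP = "^"

#: names of resources shipped with the package
SHIPPED_RESOURCES = {"consensus": "consensus_lr.csv"}


class SchemaError(ValueError):
    """A table does not have the required columns."""


def _validate_resource(df: pd.DataFrame) -> pd.DataFrame:
    missing = {"ligand", "receptor"} - set(df.columns)
    if missing:
        raise SchemaError(
            f"LR resource is missing required column(s): {sorted(missing)}"
        )
    df = df[["ligand", "receptor"]].astype(str)
    if len(df) == 0:
        raise ValueError("LR resource is empty")
    for col in ("ligand", "receptor"):
        bad = df[col].str.strip().eq("") | df[col].isna()
        if bad.any():
            raise ValueError(f"LR resource has empty {col} identifiers")
    n_dup = df.duplicated(subset=["ligand", "receptor"]).sum()
    if n_dup:
        logger.warning("dropping %d duplicate ligand-receptor rows", n_dup)
        df = df.drop_duplicates(subset=["ligand", "receptor"])
    return df.reset_index(drop=True)


def load_resource(path_or_name: str | Path = "consensus") -> pd.DataFrame:
    """Load and validate a ligand-receptor resource.

    Parameters
    ----------
    path_or_name
        Either the name of a shipped resource (``"consensus"``) or a path
        to a delimited file (CSV or TSV, sniffed from the extension) with
        ``ligand`` and ``receptor`` columns.

    Returns
    -------
    DataFrame with columns ``ligand`` and ``receptor``, duplicates dropped.
    """
    name = str(path_or_name)
    if name in SHIPPED_RESOURCES:
        ref = _ilr.files("cellcomm.data") / SHIPPED_RESOURCES[name]
        with _ilr.as_file(ref) as fp:
            df = pd.read_csv(fp)
    else:
        path = Path(path_or_name)
        if not path.exists():
            raise FileNotFoundError(
                f"{path!s} is neither a file nor a shipped resource "
                f"({sorted(SHIPPED_RESOURCES)})"
            )
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        df = pd.read_csv(path, sep=sep)
    return _validate_resource(df)


def split_complex(complex_id: str) -> list[str]:
    """Split a complex identifier into its subunit gene symbols."""
    subunits = str(complex_id).split(COMPLEX_SEP)
    if any(s == "" for s in subunits):
        raise ValueError(f"malformed complex identifier: {complex_id!r}")
    return subunits


def pair_id(ligand: str, receptor: str) -> str:
    return f"{ligand}{LR_SEP}{receptor}"


def expand_complexes(resource: pd.DataFrame) -> dict[str, tuple[list[str], list[str]]]:
    """Map each pair identifier to its (ligand subunits, receptor subunits).

    Subunit order follows the complex identifier; the ligand side comes
    first.  Raises ``ValueError`` on empty subunit tokens (e.g. ``"A_"``).
    """
    out: dict[str, tuple[list[str], list[str]]] = {}
    for lig, rec in zip(resource["ligand"], resource["receptor"]):
        out[pair_id(lig, rec)] = (split_complex(lig), split_complex(rec))
    return out


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read pathway gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise SchemaError(f"GMT line has fewer than 3 fields: {line[:60]!r}")
        name, genes = fields[0], {g for g in fields[2:] if g}
        if name in sets:
            raise ValueError(f"duplicate gene-set name in GMT: {name!r}")
        if not genes:
            raise ValueError(f"empty gene set in GMT: {name!r}")
        sets[name] = genes
    return sets


def build_lr_pathway_sets(
    resource: pd.DataFrame, gene_sets: dict[str, set[str]]
) -> dict[str, set[str]]:
    """Assign LR pairs to pathways by full-membership of all subunit genes.

    A pair belongs to a pathway iff every subunit gene of both the ligand
    and the receptor complex is in that pathway's gene set.  Pathways may
    end up with empty LR sets; they are kept (downstream size filters deal
    with them).
    """
    expanded = expand_complexes(resource)
    lr_sets: dict[str, set[str]] = {}
    for pw, genes in gene_sets.items():
        members = {
            pid
            for pid, (lig_sub, rec_sub) in expanded.items()
            if all(g in genes for g in lig_sub) and all(g in genes for g in rec_sub)
        }
        lr_sets[pw] = members
    return lr_sets


def build_weighted_lr_sets(
    resource: pd.DataFrame, net: pd.DataFrame
) -> pd.DataFrame:
    """Derive signed pathway weights for LR pairs from a weighted gene network.

    ``net`` has columns ``source`` (pathway), ``target`` (gene) and
    ``weight``.  Per pathway, subunit weights are averaged within each
    complex first, and the pair weight is the mean of the ligand-complex and
    receptor-complex weights.  A pair is retained for a pathway only if all
    participating genes have a row for that pathway and all their weights
    share one sign (zero weights are sign-incoherent with everything).

    Returns a long DataFrame with columns ``source`` (pathway),
    ``interaction`` (pair identifier) and ``weight``.
    """
    missing = {"source", "target", "weight"} - set(net.columns)
    if missing:
        raise SchemaError(f"weighted network missing column(s): {sorted(missing)}")
    if not pd.api.types.is_numeric_dtype(net["weight"]):
        raise ValueError("network weights must be numeric")
    import numpy as np

    if not np.isfinite(net["weight"]).all():
        raise ValueError("network weights must be finite")
    dup = net.duplicated(subset=["source", "target"])
    if dup.any():
        conflicting = net.loc[dup, ["source", "target"]].drop_duplicates()
        raise ValueError(
            "duplicate (pathway, gene) rows in weighted network: "
            f"{conflicting.to_records(index=False).tolist()[:5]}"
        )

    weights: dict[str, dict[str, float]] = {}
    for pw, grp in net.groupby("source"):
        weights[str(pw)] = dict(zip(grp["target"].astype(str), grp["weight"]))

    expanded = expand_complexes(resource)
    rows = []
    for pw, wmap in weights.items():
        for pid, (lig_sub, rec_sub) in expanded.items():
            genes = lig_sub + rec_sub
            if not all(g in wmap for g in genes):
                continue
            ws = [wmap[g] for g in genes]
            if not (all(w > 0 for w in ws) or all(w < 0 for w in ws)):
                continue
            lig_w = sum(wmap[g] for g in lig_sub) / len(lig_sub)
            rec_w = sum(wmap[g] for g in rec_sub) / len(rec_sub)
            rows.append((pw, pid, (lig_w + rec_w) / 2.0))
    return pd.DataFrame(rows, columns=["source", "interaction", "weight"])
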