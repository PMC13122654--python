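"""Readers and writers for the tabular formats the pipeline touches.

Expression matrices and DE tables travel as TSV, gene sets as GMT, the
pipeline configuration as YAML and the run report as JSON.  Missing protein
abundances are encoded ``NA`` on write; ``NA`` and the empty string are both
accepted on read.  Validation failures raise before anything is returned, so
a table is never partially loaded.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._stats import bh_adjust
from .containers import DeTable, ExpressionMatrix, GeneSetCollection
from .errors import FormatError, ValidationError

__all__ = [
    "read_groups_tsv",
    "write_groups_tsv",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_de_table",
    "write_de_table",
    "read_yaml",
    "write_json",
]

_NA_VALUES = ["NA", ""]

# Documented header synonyms for externally produced DE tables (matched
# case-insensitively after lowercasing).
_DE_COLUMN_SYNONYMS = {
    "gene": "gene",
    "symbol": "gene",
    "log2fc": "log2fc",
    "log2foldchange": "log2fc",
    "logfc": "log2fc",
    "pvalue": "pvalue",
    "p.value": "pvalue",
    "pval": "pvalue",
    "padj": "padj",
    "adj.p.val": "padj",
    "adjusted_pvalue": "padj",
    "qvalue": "padj",
}


def read_groups_tsv(path: str | Path) -> pd.Series:
    """Two-column TSV (sample, group) → Series sample → group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: group file needs two columns (sample, group)")
    sample, group = df.columns[:2]
    if df[sample].duplicated().any():
        dup = df[sample][df[sample].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate sample ID {dup!r} in group file")
    return pd.Series(df[group].values, index=df[sample].values, name="group")


def write_groups_tsv(groups: pd.Series, path: str | Path) -> None:
    out = pd.DataFrame({"sample": groups.index, "group": groups.values})
    out.to_csv(path, sep="\t", index=False)


def read_expression_tsv(
    path: str | Path,
    layer: str,
    groups: pd.Series | None = None,
    groups_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a features × samples TSV (first column ``gene``).

    Counts layers reject non-integer and negative entries; protein layers
    accept ``NA`` missing values.  Group labels come from `groups` or from a
    companion two-column TSV at `groups_path`.
    """
    with open(path) as fh:  # pandas mangles duplicate headers, so check raw
        header = fh.readline().rstrip("\n").split("\t")
    raw_samples = header[1:]
    dupes = {s for s in raw_samples if raw_samples.count(s) > 1}
    if dupes:
        raise FormatError(f"{path}: duplicate sample column {sorted(dupes)[0]!r}")
    df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a gene column plus at least one sample")
    gene_col = df.columns[0]
    sample_cols = pd.Index(df.columns[1:])
    values = df.set_index(gene_col)[list(sample_cols)].astype(float)
    values.index = values.index.astype(str)
    values.index.name = "gene"

    if layer == "mrna":
        arr = values.to_numpy()
        if np.isnan(arr).any():
            raise ValidationError(f"{path}: missing values are not allowed in a counts matrix")
        if (arr < 0).any():
            raise ValidationError(f"{path}: negative counts present")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError(f"{path}: counts must be integers")
        values = values.round().astype(np.int64).astype(float)
    elif layer == "protein":
        arr = values.to_numpy()
        finite = arr[np.isfinite(arr)]
        if finite.size and (finite <= 0).any():
            raise ValidationError(f"{path}: protein abundances must be positive")
    else:
        raise ValidationError(f"unknown layer {layer!r}")

    if groups is None:
        if groups_path is None:
            raise ValidationError("group labels required: pass groups or groups_path")
        groups = read_groups_tsv(groups_path)
    return ExpressionMatrix(values=values, groups=groups, layer=layer)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    if matrix.layer == "mrna":
        out = out.astype(np.int64)
    out.index.name = "gene"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name TAB description TAB member [TAB member ...]."""
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, description = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = tuple(dict.fromkeys(m for m in fields[2:] if m))
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = (description, members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (description, members) in collection.sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_de_table(
    path: str | Path,
    layer: str,
    log2fc_cutoff: float,
    alpha: float = 0.05,
    p_policy: str = "adjusted",
) -> DeTable:
    """Ingest an externally produced DE table (e.g. a DESeq2 export).

    Columns gene/log2fc/pvalue/padj are matched case-insensitively with
    documented synonyms.  Status is recomputed from the thresholds, never
    trusted from the file.
    """
    df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in _DE_COLUMN_SYNONYMS:
            rename[col] = _DE_COLUMN_SYNONYMS[key]
    df = df.rename(columns=rename)
    required = ["gene", "log2fc", "pvalue", "padj"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if df["gene"].duplicated().any():
        dup = df["gene"][df["gene"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate gene symbol {dup!r}")
    for col in ("pvalue", "padj"):
        bad = df[(df[col] < 0) | (df[col] > 1)]
        if len(bad):
            raise ValidationError(f"{path}: {col} outside [0, 1] for {bad['gene'].iloc[0]!r}")
    offending = df[df["padj"] < df["pvalue"] - 1e-12]
    if len(offending):
        raise ValidationError(
            f"{path}: adjusted p smaller than raw p for {offending['gene'].iloc[0]!r}"
        )
    table = df.set_index("gene")[["log2fc", "pvalue", "padj"]].astype(float)
    table["status"] = "NS"
    de = DeTable(
        table=table, layer=layer, log2fc_cutoff=log2fc_cutoff, alpha=alpha, p_policy=p_policy
    )
    de.recompute_status()
    return de


def write_de_table(de: DeTable, path: str | Path) -> None:
    out = de.table.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: expected a YAML mapping")
    return data


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (np.ndarray,)):
        return value.tolist()
    if isinstance(value, (set, frozenset, tuple)):
        return sorted(value) if isinstance(value, (set, frozenset)) else list(value)
    raise TypeError(f"not JSON serializable: {type(value)}")


# re-export for pipeline convenience
def recompute_bh(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a DE table with padj recomputed by BH over its rows."""
    out = table.copy()
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    return out
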