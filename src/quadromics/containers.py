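"""In-memory carriers shared by every stage.

``ExpressionMatrix`` holds a features × samples table plus a sample → group
mapping and is used for both raw counts (mRNA layer) and protein abundances
(protein layer, missing values allowed as NaN).  ``DeTable`` is the
per-feature differential-expression result of either layer; the Up/Down/NS
status column is always a pure function of (log2FC, the layer's p-value
policy, the thresholds) and is recomputed rather than trusted from files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "GROUP_REFERENCE",
    "GROUP_TREATMENT",
    "STATUS_UP",
    "STATUS_DOWN",
    "STATUS_NS",
    "call_status",
    "ExpressionMatrix",
    "DeTable",
    "GeneSetCollection",
]

# Group labels of the two-arm design: GRA is the reference (ad libitum grazing)
# arm, SUP the treatment (supplemented) arm; log2FC is always SUP minus GRA.
GROUP_REFERENCE = "GRA"
GROUP_TREATMENT = "SUP"

STATUS_UP = "Up"
STATUS_DOWN = "Down"
STATUS_NS = "NS"


def call_status(log2fc: float, p: float, log2fc_cutoff: float, alpha: float) -> str:
    """Differential status at strict cutoffs: |log2FC| > cutoff AND p < alpha."""
    if not np.isfinite(p) or not np.isfinite(log2fc) or p >= alpha:
        return STATUS_NS
    if log2fc > log2fc_cutoff:
        return STATUS_UP
    if log2fc < -log2fc_cutoff:
        return STATUS_DOWN
    return STATUS_NS


@dataclass
class ExpressionMatrix:
    """Features × samples numeric table with group labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with sample IDs as columns. Counts
        layers hold nonnegative integers; protein layers hold positive reals
        with NaN marking missing quantifications.
    groups
        Series mapping each sample ID to its group label.
    layer
        ``"mrna"`` or ``"protein"``.
    """

    values: pd.DataFrame
    groups: pd.Series
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in ("mrna", "protein"):
            raise ValidationError(f"unknown layer {self.layer!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample ID {dup!r}")
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])[:5]
            raise ValidationError(f"samples without a group label: {missing}")
        levels = self.groups.unique()
        if len(levels) != 2:
            raise ValidationError(
                f"expected exactly two groups, found {sorted(map(str, levels))}"
            )

    @property
    def gene_symbols(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in(self, group: str) -> list[str]:
        sel = self.groups.index[self.groups == group]
        return list(sel)

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[self.samples_in(group)]

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, groups=self.groups.copy(), layer=self.layer)


@dataclass
class DeTable:
    """Per-feature differential-expression results for one omics layer.

    ``table`` columns: gene (index), log2fc, pvalue, padj, status.
    """

    table: pd.DataFrame
    layer: str
    log2fc_cutoff: float
    alpha: float
    p_policy: str = "adjusted"

    def __post_init__(self) -> None:
        if self.p_policy not in ("adjusted", "raw"):
            raise ValidationError(f"p_policy must be 'adjusted' or 'raw', got {self.p_policy!r}")
        required = {"log2fc", "pvalue", "padj", "status"}
        if not required.issubset(self.table.columns):
            raise ValidationError(f"DE table missing columns {sorted(required - set(self.table.columns))}")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def decision_p(self) -> pd.Series:
        """The p-value column the status policy uses."""
        return self.table["padj"] if self.p_policy == "adjusted" else self.table["pvalue"]

    def n_by_status(self) -> dict[str, int]:
        counts = self.table["status"].value_counts()
        return {s: int(counts.get(s, 0)) for s in (STATUS_UP, STATUS_DOWN, STATUS_NS)}

    def recompute_status(self) -> None:
        p = self.decision_p().to_numpy(dtype=float)
        fc = self.table["log2fc"].to_numpy(dtype=float)
        self.table["status"] = [
            call_status(f, q, self.log2fc_cutoff, self.alpha) for f, q in zip(fc, p)
        ]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): name → (description, members)."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if len(members) == 0:
                raise ValidationError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)
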