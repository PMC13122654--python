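"""Nine-quadrant classification of matched gene–protein pairs.

The two DE layers are inner-joined on gene symbol and every pair is placed
in the 3 × 3 grid of (mRNA status, protein status):

    Q1 Down/Up    discordant (post-transcriptional up)
    Q2 NS/Up      protein-only up
    Q3 Up/Up      concordant up
    Q4 Down/NS    mRNA-only down
    Q5 NS/NS      no significant change
    Q6 Up/NS      mRNA-only up
    Q7 Down/Down  concordant down
    Q8 NS/Down    protein-only down
    Q9 Up/Down    discordant (post-transcriptional down)

Summaries report quadrant counts, the changed fraction (everything outside
Q5), and the regulatory-mode shares among changed pairs (concordant Q3+Q7,
protein-only Q2+Q8, mRNA-only Q4+Q6, discordant Q1+Q9).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._stats import pct
from .containers import STATUS_DOWN, STATUS_NS, STATUS_UP, DeTable
from .errors import PipelineError, ValidationError
from .simulate import QUADRANTS

__all__ = [
    "classify_quadrant",
    "match_pairs",
    "classify_pairs",
    "QuadrantSummary",
    "summarize_quadrants",
    "select_label_genes",
]

_GRID: dict[tuple[str, str], str] = {
    (STATUS_DOWN, STATUS_UP): "Q1",
    (STATUS_NS, STATUS_UP): "Q2",
    (STATUS_UP, STATUS_UP): "Q3",
    (STATUS_DOWN, STATUS_NS): "Q4",
    (STATUS_NS, STATUS_NS): "Q5",
    (STATUS_UP, STATUS_NS): "Q6",
    (STATUS_DOWN, STATUS_DOWN): "Q7",
    (STATUS_NS, STATUS_DOWN): "Q8",
    (STATUS_UP, STATUS_DOWN): "Q9",
}

# ranking axis for representative labels: these quadrants rank by |mRNA log2FC|,
# Q2/Q8 by |protein log2FC|; Q3/Q7 are exhaustively labeled instead.
_MRNA_RANKED = {"Q1", "Q4", "Q6", "Q9"}
_PROTEIN_RANKED = {"Q2", "Q8"}
_CONCORDANT = {"Q3", "Q7"}


def classify_quadrant(mrna_status: str, protein_status: str) -> str:
    """Quadrant label for one (mRNA status, protein status) combination."""
    try:
        return _GRID[(mrna_status, protein_status)]
    except KeyError:
        raise ValidationError(
            f"invalid status pair ({mrna_status!r}, {protein_status!r})"
        ) from None


def match_pairs(mrna: DeTable, protein: DeTable) -> pd.DataFrame:
    """Inner join of the two DE layers on exact gene-symbol equality.

    Returns a DataFrame indexed by gene with columns mrna_log2fc,
    mrna_status, protein_log2fc, protein_status (quadrant unset).
    """
    for name, de in (("mRNA", mrna), ("protein", protein)):
        if de.genes.duplicated().any():
            dup = de.genes[de.genes.duplicated()][0]
            raise ValidationError(f"{name} DE table contains duplicate symbol {dup!r}")
    shared = mrna.genes.intersection(protein.genes)
    if len(shared) == 0:
        raise PipelineError(
            "no overlap between the two layers; "
            f"mRNA examples: {list(mrna.genes[:5])}, protein examples: {list(protein.genes[:5])}"
        )
    pairs = pd.DataFrame(
        {
            "mrna_log2fc": mrna.table.loc[shared, "log2fc"],
            "mrna_status": mrna.table.loc[shared, "status"],
            "protein_log2fc": protein.table.loc[shared, "log2fc"],
            "protein_status": protein.table.loc[shared, "status"],
        }
    )
    pairs.index.name = "gene"
    return pairs.sort_index()


def classify_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Add the quadrant column; returns a copy."""
    out = pairs.copy()
    out["quadrant"] = [
        classify_quadrant(m, p) for m, p in zip(out["mrna_status"], out["protein_status"])
    ]
    return out


@dataclass
class QuadrantSummary:
    """Counts and percentage rendering of a classified pair table.

    Percentages of the total are rendered at 2 decimals, shares of the
    changed pairs at 1 decimal (half-up); raw fractions are retained in
    ``fractions``.
    """

    counts: dict[str, int]
    n_total: int
    n_changed: int
    pct_of_total: dict[str, float]
    pct_changed_of_total: float
    pct_changed_concordant: float
    pct_changed_protein_only: float
    pct_changed_mrna_only: float
    pct_changed_discordant: float
    degenerate: bool = False
    fractions: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_quadrants(pairs: pd.DataFrame) -> QuadrantSummary:
    """Quadrant composition summary of a classified pair table."""
    if "quadrant" not in pairs.columns:
        raise ValidationError("pairs must be classified before summarizing")
    vc = pairs["quadrant"].value_counts()
    counts = {q: int(vc.get(q, 0)) for q in QUADRANTS}
    n_total = int(len(pairs))
    n_changed = n_total - counts["Q5"]
    concordant = counts["Q3"] + counts["Q7"]
    protein_only = counts["Q2"] + counts["Q8"]
    mrna_only = counts["Q4"] + counts["Q6"]
    discordant = counts["Q1"] + counts["Q9"]
    fractions = {
        "changed_of_total": n_changed / n_total if n_total else 0.0,
        "concordant_of_changed": concordant / n_changed if n_changed else 0.0,
        "protein_only_of_changed": protein_only / n_changed if n_changed else 0.0,
        "mrna_only_of_changed": mrna_only / n_changed if n_changed else 0.0,
        "discordant_of_changed": discordant / n_changed if n_changed else 0.0,
    }
    return QuadrantSummary(
        counts=counts,
        n_total=n_total,
        n_changed=n_changed,
        pct_of_total={q: pct(counts[q], n_total, 2) for q in QUADRANTS},
        pct_changed_of_total=pct(n_changed, n_total, 2),
        pct_changed_concordant=pct(concordant, n_changed, 1),
        pct_changed_protein_only=pct(protein_only, n_changed, 1),
        pct_changed_mrna_only=pct(mrna_only, n_changed, 1),
        pct_changed_discordant=pct(discordant, n_changed, 1),
        degenerate=n_changed == 0,
        fractions=fractions,
    )


def select_label_genes(pairs: pd.DataFrame, top_m: int = 3) -> pd.DataFrame:
    """Hierarchical plot-label selection.

    All Q3/Q7 pairs are labeled ``concordant``; in each remaining changed
    quadrant the top `top_m` pairs on the quadrant's ranking axis (|mRNA
    log2FC| for Q1/Q4/Q6/Q9, |protein log2FC| for Q2/Q8) are labeled
    ``representative``.  Ties break by symbol lexicographic order.
    """
    if "quadrant" not in pairs.columns:
        raise ValidationError("pairs must be classified before labeling")
    picked = []
    for quadrant, sub in pairs.groupby("quadrant"):
        if quadrant in _CONCORDANT:
            chosen = sub.copy()
            chosen["label_class"] = "concordant"
        elif quadrant in _MRNA_RANKED or quadrant in _PROTEIN_RANKED:
            axis = "mrna_log2fc" if quadrant in _MRNA_RANKED else "protein_log2fc"
            # sub is symbol-sorted; a stable sort on descending magnitude
            # therefore breaks ties lexicographically by symbol
            sub = sub.sort_index()
            ranked = sub.loc[
                sub[axis].abs().sort_values(ascending=False, kind="mergesort").index
            ]
            chosen = ranked.head(top_m).copy()
            chosen["label_class"] = "representative"
        else:  # Q5 never labeled
            continue
        picked.append(chosen)
    if not picked:
        return pairs.iloc[0:0].assign(label_class=pd.Series(dtype=str))
    return pd.concat(picked).sort_index()
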