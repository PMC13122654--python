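"""Cross-omics biomarker evaluation: Pearson correlation with Fisher-z
confidence intervals, ROC AUC with DeLong confidence intervals, and AUC
banding.

AUC is the Mann–Whitney probability that a treatment-group sample scores
above a reference-group sample (ties counted ½), computed from midranks.
Scores are used as-is — no orientation flipping — so markers that score
lower in the positive class legitimately report AUC < 0.5.  The DeLong
variance uses the structural components of the placement values; a
perfectly separated marker has SE 0 and a degenerate CI at the point
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import round_half_up
from .containers import GROUP_TREATMENT, ExpressionMatrix
from .errors import ValidationError

__all__ = [
    "pearson_ci",
    "auc_delong",
    "categorize_auc",
    "BiomarkerRecord",
    "evaluate_candidates",
    "mean_auc",
]


def pearson_ci(x, y, level: float = 0.95) -> tuple[float, tuple[float, float], float]:
    """Pearson r with Fisher-z confidence interval and two-sided t-test p.

    The CI transforms r with atanh, uses SE 1/sqrt(n−3), and back-transforms;
    the p-value uses t = r·sqrt(n−2)/sqrt(1−r²) on n−2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 4:
        raise ValidationError("need at least 4 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("correlation undefined for a constant vector")

    r = float(np.corrcoef(x, y)[0, 1])
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    if abs(r) == 1.0:
        ci = (r, r)
    else:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        ci = (float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se)))
    return r, ci, p


def auc_delong(
    scores,
    labels,
    positive_group: str = GROUP_TREATMENT,
    level: float = 0.95,
) -> tuple[float, tuple[float, float], float]:
    """ROC AUC via midranks with a DeLong confidence interval.

    Returns (auc, (lo, hi), se).  Both classes must be present and scores
    complete.  The CI is auc ± z·SE truncated to [0, 1]; perfect separation
    yields SE 0 and a point CI.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.ndim != 1 or scores.shape != labels.shape:
        raise ValidationError("scores and labels must be 1-D arrays of equal length")
    if np.isnan(scores).any():
        raise ValidationError("missing scores are not allowed")
    is_pos = labels == positive_group
    m = int(is_pos.sum())
    n = int((~is_pos).sum())
    if m == 0 or n == 0:
        raise ValidationError(f"both classes required (positive={positive_group!r})")

    pos = scores[is_pos]
    neg = scores[~is_pos]

    # midrank AUC
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    auc = float((all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n))

    # DeLong structural components (placements)
    # V10_i = P(neg < pos_i) + 0.5 P(neg == pos_i); V01_j analogous
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))

    if se == 0.0:
        ci = (auc, auc)
    else:
        zcrit = stats.norm.ppf(0.5 + level / 2.0)
        ci = (max(0.0, auc - zcrit * se), min(1.0, auc + zcrit * se))
    return auc, ci, se


def categorize_auc(auc: float) -> str:
    """Diagnostic band: left-closed intervals [0.9,1] excellent, [0.8,0.9)
    good, [0.7,0.8) acceptable, [0,0.7) poor."""
    if not 0.0 <= auc <= 1.0:
        raise ValidationError(f"AUC outside [0, 1]: {auc}")
    if auc >= 0.9:
        return "excellent"
    if auc >= 0.8:
        return "good"
    if auc >= 0.7:
        return "acceptable"
    return "poor"


@dataclass
class BiomarkerRecord:
    """Cross-omics evaluation of one candidate gene.

    Fields are ``None`` where the gene is absent from the relevant layer
    (reported as not detected rather than an error).
    """

    gene_symbol: str
    detected_mrna: bool
    detected_protein: bool
    r: float | None = None
    r_ci: tuple[float, float] | None = None
    r_p: float | None = None
    auc_mrna: float | None = None
    auc_mrna_ci: tuple[float, float] | None = None
    category_mrna: str | None = None
    auc_protein: float | None = None
    auc_protein_ci: tuple[float, float] | None = None
    category_protein: str | None = None


def evaluate_candidates(
    candidates,
    mrna_matrix: ExpressionMatrix | None,
    protein_matrix: ExpressionMatrix | None,
    positive_group: str = GROUP_TREATMENT,
    level: float = 0.95,
) -> list[BiomarkerRecord]:
    """Per-candidate cross-omics correlation and per-layer ROC evaluation.

    The correlation pairs each sample's mRNA and protein value (samples
    shared by both layers); AUC treats `positive_group` as the positive
    class.  A candidate absent from a layer gets ``None`` fields there.
    """
    records: list[BiomarkerRecord] = []
    shared_samples: list[str] = []
    if mrna_matrix is not None and protein_matrix is not None:
        shared_samples = [
            s for s in mrna_matrix.sample_ids if s in set(protein_matrix.sample_ids)
        ]
    for gene in candidates:
        in_mrna = mrna_matrix is not None and gene in mrna_matrix.values.index
        in_protein = protein_matrix is not None and gene in protein_matrix.values.index
        record = BiomarkerRecord(
            gene_symbol=gene, detected_mrna=bool(in_mrna), detected_protein=bool(in_protein)
        )
        if in_mrna:
            scores = mrna_matrix.values.loc[gene].to_numpy(dtype=float)
            auc, ci, _ = auc_delong(
                scores, mrna_matrix.groups.to_numpy(), positive_group, level
            )
            record.auc_mrna, record.auc_mrna_ci = auc, ci
            record.category_mrna = categorize_auc(auc)
        if in_protein:
            scores = protein_matrix.values.loc[gene].to_numpy(dtype=float)
            auc, ci, _ = auc_delong(
                scores, protein_matrix.groups.to_numpy(), positive_group, level
            )
            record.auc_protein, record.auc_protein_ci = auc, ci
            record.category_protein = categorize_auc(auc)
        if in_mrna and in_protein and len(shared_samples) >= 4:
            x = mrna_matrix.values.loc[gene, shared_samples].to_numpy(dtype=float)
            y = protein_matrix.values.loc[gene, shared_samples].to_numpy(dtype=float)
            if np.std(x) > 0 and np.std(y) > 0:
                record.r, record.r_ci, record.r_p = pearson_ci(x, y, level)
        records.append(record)
    return records


def mean_auc(records: list[BiomarkerRecord], layer: str, decimals: int = 2) -> float:
    """Column mean of the per-layer AUCs over detected candidates (half-up)."""
    attr = {"mrna": "auc_mrna", "protein": "auc_protein"}[layer]
    values = [getattr(r, attr) for r in records if getattr(r, attr) is not None]
    if not values:
        raise ValidationError(f"no AUC values available for layer {layer!r}")
    return round_half_up(float(np.mean(values)), decimals)


def records_to_frame(records: list[BiomarkerRecord]) -> pd.DataFrame:
    """Tabular (report-shaped) view of biomarker records."""
    rows = []
    for r in records:
        rows.append(
            {
                "gene": r.gene_symbol,
                "r": r.r,
                "r_ci_low": r.r_ci[0] if r.r_ci else None,
                "r_ci_high": r.r_ci[1] if r.r_ci else None,
                "r_p": r.r_p,
                "auc_mrna": r.auc_mrna,
                "auc_mrna_ci_low": r.auc_mrna_ci[0] if r.auc_mrna_ci else None,
                "auc_mrna_ci_high": r.auc_mrna_ci[1] if r.auc_mrna_ci else None,
                "category_mrna": r.category_mrna if r.detected_mrna else "Not detected",
                "auc_protein": r.auc_protein,
                "auc_protein_ci_low": r.auc_protein_ci[0] if r.auc_protein_ci else None,
                "auc_protein_ci_high": r.auc_protein_ci[1] if r.auc_protein_ci else None,
                "category_protein": r.category_protein if r.detected_protein else "Not detected",
            }
        )
    return pd.DataFrame(rows).set_index("gene")
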