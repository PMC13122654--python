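"""Proteomic preprocessing (filtering, kNN imputation, normalization) and DEP calling.

The fixed stage order is filter → impute → normalize → test.  Filtering drops
``LOC``-prefixed (unannotated) proteins and any protein missing in strictly
more than half the samples.  Imputation replaces each missing entry with the
average of that sample's values over the k nearest proteins; distances are
computed on the log2 scale over mutually observed samples (scaled by overlap
size), and only proteins observed in the target sample are eligible donors.
Abundances are then log2-transformed and per-sample median-centered, and
differential proteins are called with a pooled-variance two-tailed Student
t-test plus Benjamini–Hochberg correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.impute import KNNImputer

from ._stats import bh_adjust
from .containers import (
    GROUP_REFERENCE,
    GROUP_TREATMENT,
    DeTable,
    ExpressionMatrix,
    call_status,
)
from .errors import ConfigurationError, PipelineError, ValidationError

__all__ = [
    "ProteomePrepReport",
    "filter_proteins",
    "impute_knn",
    "normalize_log_median",
    "protein_de",
    "cv_below_fraction",
]

logger = logging.getLogger(__name__)

_CV_THRESHOLD = 0.3


@dataclass
class ProteomePrepReport:
    """Bookkeeping of proteome preprocessing.

    ``n_imputed_cells`` counts the missing cells among retained proteins
    (each will be filled by imputation); ``cv_below_03`` is the per-group
    fraction of retained proteins with a within-group coefficient of
    variation below 0.3, computed on the observed raw abundances.
    """

    n_input: int
    n_loc_removed: int
    n_missingness_removed: int
    n_imputed_cells: int
    cv_below_03: dict[str, float]

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def cv_below_fraction(matrix: ExpressionMatrix, threshold: float = _CV_THRESHOLD) -> dict[str, float]:
    """Per-group fraction of proteins with CV < threshold (NaNs ignored)."""
    out: dict[str, float] = {}
    for group in sorted(matrix.groups.unique()):
        sub = matrix.group_values(group).to_numpy(dtype=float)
        nobs = (~np.isnan(sub)).sum(axis=1)
        valid = nobs >= 2  # CV needs at least two observed values
        cv = np.full(len(sub), np.inf)
        if valid.any():
            mean = np.nanmean(sub[valid], axis=1)
            sd = np.nanstd(sub[valid], axis=1, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                cv[valid] = np.where(mean > 0, sd / mean, np.inf)
        ok = np.isfinite(cv)
        out[group] = float((cv[ok] < threshold).mean()) if ok.any() else 0.0
    return out


def filter_proteins(
    abundance: ExpressionMatrix, missing_cutoff: float = 0.5
) -> tuple[ExpressionMatrix, ProteomePrepReport]:
    """Remove LOC-prefixed proteins and those missing in > `missing_cutoff` of samples.

    The missingness rule is strict: a protein missing in exactly half of the
    samples is retained.
    """
    values = abundance.values
    n_input = len(values)

    symbols = values.index.astype(str)
    is_loc = symbols.str.startswith("LOC")
    n_loc = int(is_loc.sum())
    values = values[~is_loc]

    missing_frac = values.isna().mean(axis=1)
    keep = missing_frac <= missing_cutoff
    n_missingness = int((~keep).sum())
    values = values[keep]

    if len(values) == 0:
        raise PipelineError("no proteins survive filtering")

    retained = abundance.with_values(values)
    report = ProteomePrepReport(
        n_input=n_input,
        n_loc_removed=n_loc,
        n_missingness_removed=n_missingness,
        n_imputed_cells=int(values.isna().to_numpy().sum()),
        cv_below_03=cv_below_fraction(retained),
    )
    logger.info("filter_proteins: %s", report.to_dict())
    return retained, report


def impute_knn(abundance: ExpressionMatrix, k: int = 5) -> ExpressionMatrix:
    """k-nearest-neighbor imputation over proteins (rows).

    Distances are Euclidean on the log2 scale over samples observed in both
    rows, scaled by overlap size; donors must be observed in the target
    sample.  When fewer than k eligible donors exist the available ones are
    used and a warning is logged.  Observed cells are returned unchanged.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    values = abundance.values
    missing = values.isna()
    if not missing.to_numpy().any():
        return abundance.with_values(values.copy())
    if missing.all(axis=1).any():
        bad = values.index[missing.all(axis=1)][0]
        raise ValidationError(f"protein {bad!r} has no observed value; filter before imputing")

    observed_per_sample = (~missing).sum(axis=0)
    needy = missing.any(axis=0)
    # a donor must itself be observed in the target sample, so subtract the row
    eligible = observed_per_sample[needy] - 1
    if (eligible < k).any():
        logger.warning(
            "impute_knn: fewer than k=%d eligible neighbors for %d sample(s); using all available",
            k,
            int((eligible < k).sum()),
        )

    log2 = np.log2(values.to_numpy(dtype=float))
    imputer = KNNImputer(n_neighbors=k, weights="uniform", metric="nan_euclidean")
    filled_log2 = imputer.fit_transform(log2)
    filled = values.to_numpy(dtype=float).copy()
    mask = missing.to_numpy()
    filled[mask] = 2.0 ** filled_log2[mask]
    return abundance.with_values(pd.DataFrame(filled, index=values.index, columns=values.columns))


def normalize_log_median(abundance: ExpressionMatrix) -> ExpressionMatrix:
    """log2-transform and per-sample median-center (every sample median → 0)."""
    values = abundance.values.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValidationError("missing values present; impute before normalizing")
    if (values <= 0).any():
        raise ValidationError("nonpositive abundance; normalization requires positive values")
    log2 = np.log2(values)
    log2 = log2 - np.median(log2, axis=0, keepdims=True)
    return abundance.with_values(
        pd.DataFrame(log2, index=abundance.values.index, columns=abundance.values.columns)
    )


def protein_de(
    normalized: ExpressionMatrix,
    log2fc_cutoff: float = 0.263,
    alpha: float = 0.05,
    p_policy: str = "adjusted",
) -> DeTable:
    """Pooled-variance two-tailed Student t-test per protein with BH correction.

    log2FC is mean(SUP) − mean(GRA) on the normalized (log2) scale.  With
    zero pooled variance the p-value degenerates to 1 for equal means and to
    0 otherwise (logged).  The default significance policy uses the adjusted
    p-value; ``p_policy="raw"`` reproduces analyses thresholded on raw p.
    """
    ref_samples = normalized.samples_in(GROUP_REFERENCE)
    trt_samples = normalized.samples_in(GROUP_TREATMENT)
    if len(ref_samples) < 2 or len(trt_samples) < 2:
        raise ConfigurationError("each group needs at least 2 samples for the DE test")

    y_ref = normalized.values[ref_samples].to_numpy()
    y_trt = normalized.values[trt_samples].to_numpy()
    log2fc = y_trt.mean(axis=1) - y_ref.mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance rows
        _, pvalues = stats.ttest_ind(y_trt, y_ref, axis=1, equal_var=True)
    degenerate = ~np.isfinite(pvalues)
    if degenerate.any():
        n_zero_var_diff = int((degenerate & (np.abs(log2fc) >= 1e-12)).sum())
        if n_zero_var_diff:
            logger.warning(
                "protein_de: %d protein(s) with zero pooled variance and unequal means (p set to 0)",
                n_zero_var_diff,
            )
        pvalues = np.where(degenerate & (np.abs(log2fc) < 1e-12), 1.0, pvalues)
        pvalues = np.where(~np.isfinite(pvalues), 0.0, pvalues)

    padj = bh_adjust(pvalues)
    decision = padj if p_policy == "adjusted" else pvalues
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvalues,
            "padj": padj,
            "status": [
                call_status(f, q, log2fc_cutoff, alpha) for f, q in zip(log2fc, decision)
            ],
        },
        index=normalized.values.index.copy(),
    )
    return DeTable(
        table=table,
        layer="protein",
        log2fc_cutoff=log2fc_cutoff,
        alpha=alpha,
        p_policy=p_policy,
    )
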