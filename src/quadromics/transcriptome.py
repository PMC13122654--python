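"""Gene filtering and the mRNA-layer differential-expression stand-in.

Filtering removes genes with a total count below 10 summed over all samples,
symbols with the unannotated ``LOC``/``Novel`` prefixes, and collapses
duplicated symbols to the row with the highest mean expression.

The DE test is a documented stand-in: counts are normalized by
median-of-ratios size factors against a geometric-mean pseudo-reference
(zeros excluded from the reference), log2(x+1)-transformed, and compared
between groups with a two-sided Welch t-test, followed by Benjamini–Hochberg
adjustment across all tested genes.  Externally produced negative-binomial
DE tables can be ingested instead via :func:`quadromics.io.read_de_table`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, round_sigfig
from .containers import (
    GROUP_REFERENCE,
    GROUP_TREATMENT,
    DeTable,
    ExpressionMatrix,
    call_status,
)
from .errors import ConfigurationError, PipelineError

__all__ = [
    "GeneFilterReport",
    "filter_genes",
    "size_factors",
    "de_standin",
    "fold_change",
    "fold_change_str",
]

logger = logging.getLogger(__name__)

_EXCLUDED_PREFIXES = ("LOC", "Novel")
_MIN_TOTAL_COUNT = 10


@dataclass
class GeneFilterReport:
    """Bookkeeping of the gene-filtering stage; counts always reconcile."""

    n_input: int
    n_low_count_removed: int
    n_prefix_removed: int
    n_duplicate_collapsed: int
    n_output: int

    def __post_init__(self) -> None:
        expected = (
            self.n_input
            - self.n_low_count_removed
            - self.n_prefix_removed
            - self.n_duplicate_collapsed
        )
        assert self.n_output == expected, "filter report does not reconcile"

    def to_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def filter_genes(counts: ExpressionMatrix) -> tuple[ExpressionMatrix, GeneFilterReport]:
    """Apply the three filtering rules: low total count, prefix, duplicates.

    Genes whose counts sum to < 10 over all samples are removed; symbols
    starting with ``LOC`` or ``Novel`` (case-sensitive) are removed; when a
    symbol occurs on several rows, the row with the highest mean is kept
    (ties broken by original row order, i.e. lexicographically smallest
    original position first).
    """
    values = counts.values
    n_input = len(values)

    totals = values.sum(axis=1)
    keep_low = totals >= _MIN_TOTAL_COUNT
    n_low = int((~keep_low).sum())
    values = values[keep_low]

    symbols = values.index.astype(str)
    has_prefix = symbols.str.startswith(_EXCLUDED_PREFIXES)
    n_prefix = int(has_prefix.sum())
    values = values[~has_prefix]

    n_before_dedup = len(values)
    if values.index.duplicated().any():
        means = values.mean(axis=1).to_numpy()
        order = np.lexsort((np.arange(len(values)), -means))
        values = values.iloc[order]
        values = values[~values.index.duplicated(keep="first")]
        values = values.sort_index()
    n_dup = n_before_dedup - len(values)

    if len(values) == 0:
        raise PipelineError("no genes survive filtering")

    report = GeneFilterReport(
        n_input=n_input,
        n_low_count_removed=n_low,
        n_prefix_removed=n_prefix,
        n_duplicate_collapsed=n_dup,
        n_output=len(values),
    )
    logger.info("filter_genes: %s", report.to_dict())
    return counts.with_values(values), report


def size_factors(values: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against a geometric-mean reference.

    The per-gene reference is the geometric mean over its nonzero counts;
    each sample's factor is the median ratio count/reference over genes
    observed (nonzero) in that sample.
    """
    arr = values.to_numpy(dtype=float)
    logs = np.full(arr.shape, np.nan)
    np.log(arr, out=logs, where=arr > 0)
    n_nonzero = (arr > 0).sum(axis=1)
    usable = n_nonzero > 0
    ref = np.full(len(arr), np.nan)
    ref[usable] = np.exp(np.nansum(logs[usable], axis=1) / n_nonzero[usable])

    factors = np.ones(arr.shape[1])
    for j in range(arr.shape[1]):
        mask = (arr[:, j] > 0) & np.isfinite(ref)
        if mask.any():
            factors[j] = np.median(arr[mask, j] / ref[mask])
    # guard the degenerate all-zero-sample case
    factors[~np.isfinite(factors) | (factors <= 0)] = 1.0
    return pd.Series(factors, index=values.columns, name="size_factor")


def de_standin(
    counts: ExpressionMatrix,
    log2fc_cutoff: float = 0.585,
    alpha: float = 0.05,
) -> DeTable:
    """Welch-t stand-in DE on log2(size-factor-normalized count + 1).

    log2FC is mean(SUP) − mean(GRA) on the transformed scale; BH adjustment
    is applied across all tested genes; status uses strict cutoffs
    (|log2FC| > cutoff and adjusted p < alpha).
    """
    ref_samples = counts.samples_in(GROUP_REFERENCE)
    trt_samples = counts.samples_in(GROUP_TREATMENT)
    if len(ref_samples) < 2 or len(trt_samples) < 2:
        raise ConfigurationError("each group needs at least 2 samples for the DE test")

    sf = size_factors(counts.values)
    normalized = counts.values / sf
    y = np.log2(normalized + 1.0)
    y_ref = y[ref_samples].to_numpy()
    y_trt = y[trt_samples].to_numpy()

    log2fc = y_trt.mean(axis=1) - y_ref.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance rows
        _, pvalues = stats.ttest_ind(y_trt, y_ref, axis=1, equal_var=False)
    # zero variance in both groups: p=1 when means agree, p=0 otherwise
    degenerate = ~np.isfinite(pvalues)
    if degenerate.any():
        pvalues = np.where(degenerate & (np.abs(log2fc) < 1e-12), 1.0, pvalues)
        pvalues = np.where(~np.isfinite(pvalues), 0.0, pvalues)

    padj = bh_adjust(pvalues)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvalues,
            "padj": padj,
            "status": [
                call_status(f, q, log2fc_cutoff, alpha) for f, q in zip(log2fc, padj)
            ],
        },
        index=counts.values.index.copy(),
    )
    return DeTable(
        table=table,
        layer="mrna",
        log2fc_cutoff=log2fc_cutoff,
        alpha=alpha,
        p_policy="adjusted",
    )


def fold_change(log2fc: float) -> float:
    """Linear fold change 2**log2fc."""
    return float(2.0**log2fc)


def fold_change_str(log2fc: float, sig: int = 2) -> float:
    """Linear fold change rendered at `sig` significant figures."""
    return round_sigfig(fold_change(log2fc), sig)
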