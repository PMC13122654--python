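"""Hypergeometric over-representation, quadrant-conditioned enrichment,
two-tier core-gene selection, and the gene × pathway matrix summary.

The over-representation p-value for a query of size n drawn from a background
of size N, against a set with K background members and k overlapping query
members, is the upper hypergeometric tail P(X ≥ k) (equivalently a one-sided
Fisher exact test).  Benjamini–Hochberg adjustment runs across all tested
sets.  Quadrant-conditioned enrichment uses the full matched-pair universe as
the background and tests each changed quadrant's members separately.

Core genes are selected in two tiers: (i) hub genes appearing in at least
``min_pathways`` significantly enriched sets; (ii) if fewer than
``target_size`` hubs exist, each significant set contributes its ``top_m``
members by |log2FC| until exhausted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._stats import bh_adjust, pct
from .containers import DeTable, GeneSetCollection
from .errors import ConfigurationError, ValidationError

__all__ = [
    "EnrichmentRecord",
    "hypergeom_p",
    "enrich",
    "quadrant_enrichment",
    "CoreGeneSelection",
    "select_core_genes",
    "gene_pathway_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRecord:
    """One gene set's over-representation result against a background."""

    set_name: str
    k: int  # |query ∩ set ∩ background|
    K: int  # |set ∩ background|
    n: int  # |query ∩ background|
    N: int  # |background|
    p: float
    adj_p: float
    members: tuple[str, ...]  # overlapping gene symbols
    significant: bool = False


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """One-sided over-representation tail P(X ≥ k), X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValidationError(
            f"impossible hypergeometric configuration k={k}, K={K}, n={n}, N={N}"
        )
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query_genes,
    background_genes,
    sets: GeneSetCollection,
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Over-representation of `query_genes` in each set, within `background_genes`.

    Query genes outside the background are dropped with a logged warning
    count.  One record is produced per set with at least one background
    member; BH adjustment runs across all tested sets and records are
    flagged significant when adj_p < alpha.  Records are returned sorted by
    (p, set name).
    """
    background = set(background_genes)
    if not background:
        raise ConfigurationError("empty enrichment background")
    query = set(query_genes)
    outside = query - background
    if outside:
        logger.warning("enrich: dropping %d query gene(s) outside the background", len(outside))
        query &= background

    N = len(background)
    n = len(query)
    rows: list[EnrichmentRecord] = []
    for name in sets.names():
        members_bg = background.intersection(sets.members(name))
        if not members_bg:
            continue
        overlap = tuple(sorted(query.intersection(members_bg)))
        rows.append(
            EnrichmentRecord(
                set_name=name,
                k=len(overlap),
                K=len(members_bg),
                n=n,
                N=N,
                p=hypergeom_p(len(overlap), len(members_bg), n, N),
                adj_p=1.0,
                members=overlap,
            )
        )
    if rows:
        adj = bh_adjust([r.p for r in rows])
        for record, a in zip(rows, adj):
            record.adj_p = float(a)
            record.significant = record.adj_p < alpha
    rows.sort(key=lambda r: (r.p, r.set_name))
    return rows


def quadrant_enrichment(
    pairs: pd.DataFrame,
    sets: GeneSetCollection,
    alpha: float = 0.05,
    include_q5: bool = False,
) -> dict[str, list[EnrichmentRecord]]:
    """Per-quadrant enrichment against the full matched-pair background.

    Every non-empty quadrant except Q5 (unless `include_q5`) is tested with
    its member symbols as the query and all pair symbols as the background.
    Empty quadrants map to empty lists.
    """
    if "quadrant" not in pairs.columns:
        raise ValidationError("pairs must be classified before enrichment")
    background = list(pairs.index)
    out: dict[str, list[EnrichmentRecord]] = {}
    for quadrant, sub in pairs.groupby("quadrant"):
        if quadrant == "Q5" and not include_q5:
            continue
        out[str(quadrant)] = enrich(list(sub.index), background, sets, alpha=alpha)
    return out


@dataclass
class CoreGeneSelection:
    """Result of the two-tier core-gene strategy."""

    hub_genes: tuple[str, ...]
    supplemental_genes: tuple[str, ...]
    connectivity: dict[str, int]
    n_enriched_genes: int  # union of members across significant sets
    selection_rate_pct: float  # selected / enriched, rendered at 2 decimals
    matrix_density: float | None = None
    down_share: float | None = None
    significant_sets: tuple[str, ...] = field(default_factory=tuple)

    @property
    def selected(self) -> tuple[str, ...]:
        return self.hub_genes + self.supplemental_genes


def select_core_genes(
    records: list[EnrichmentRecord],
    de: DeTable,
    min_pathways: int = 2,
    target_size: int = 20,
    top_m: int = 3,
    alpha: float = 0.05,
) -> CoreGeneSelection:
    """Two-tier selection: hubs in ≥ `min_pathways` significant sets, then
    per-set top-`top_m` |log2FC| supplementation while |selection| < `target_size`.

    Connectivity is counted over significant records only.  With no
    significant record the selection is empty (warning logged).
    """
    significant = [r for r in records if r.adj_p < alpha]
    if not significant:
        logger.warning("select_core_genes: no significant enrichment records")
        return CoreGeneSelection(
            hub_genes=(),
            supplemental_genes=(),
            connectivity={},
            n_enriched_genes=0,
            selection_rate_pct=0.0,
        )
    significant.sort(key=lambda r: (r.p, r.set_name))

    connectivity: dict[str, int] = {}
    for record in significant:
        for gene in record.members:
            connectivity[gene] = connectivity.get(gene, 0) + 1
    enriched_genes = sorted(connectivity)

    hubs = sorted(
        (g for g, c in connectivity.items() if c >= min_pathways),
        key=lambda g: (-connectivity[g], g),
    )

    log2fc = de.table["log2fc"]
    supplemental: list[str] = []
    if len(hubs) < target_size:
        selected = set(hubs)
        for record in significant:
            ranked = sorted(
                record.members,
                key=lambda g: (-abs(float(log2fc.get(g, 0.0))), g),
            )
            added = 0
            for gene in ranked:
                if gene in selected:
                    continue
                supplemental.append(gene)
                selected.add(gene)
                added += 1
                if added >= top_m:
                    break

    n_selected = len(hubs) + len(supplemental)
    return CoreGeneSelection(
        hub_genes=tuple(hubs),
        supplemental_genes=tuple(supplemental),
        connectivity=connectivity,
        n_enriched_genes=len(enriched_genes),
        selection_rate_pct=pct(n_selected, len(enriched_genes), 2),
        significant_sets=tuple(r.set_name for r in significant),
    )


def gene_pathway_matrix(
    selection: CoreGeneSelection,
    records: list[EnrichmentRecord],
    de: DeTable,
) -> tuple[pd.DataFrame, float, float]:
    """Gene × pathway log2FC matrix plus (density %, down-regulated share %).

    Rows are the selected genes, columns the significant sets; a cell holds
    the gene's log2FC where the gene overlaps the set and NaN otherwise.
    Density is the percentage of non-missing cells; down_share the
    percentage of non-missing cells with negative log2FC (both rendered at
    1 decimal).  The raw values are also written back onto `selection`.
    """
    genes = list(selection.selected)
    if not genes:
        raise ValidationError("empty core-gene selection")
    by_name = {r.set_name: r for r in records}
    set_names = [s for s in selection.significant_sets if s in by_name]
    log2fc = de.table["log2fc"]
    matrix = pd.DataFrame(np.nan, index=pd.Index(genes, name="gene"), columns=set_names)
    for name in set_names:
        members = set(by_name[name].members)
        for gene in genes:
            if gene in members:
                matrix.loc[gene, name] = float(log2fc.get(gene, np.nan))
    filled = matrix.notna().to_numpy()
    n_filled = int(filled.sum())
    density = pct(n_filled, matrix.size, 1)
    n_down = int((matrix.to_numpy() < 0).sum())
    down_share = pct(n_down, n_filled, 1) if n_filled else 0.0
    selection.matrix_density = density
    selection.down_share = down_share
    return matrix, density, down_share
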