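"""End-to-end orchestration: filter → DE (both layers) → match → classify →
summarize → quadrant enrichment → core genes → biomarker evaluation.

The pipeline is driven by a single :class:`PipelineConfig` (YAML-loadable);
every stage writes its tabular output under ``output_dir`` and the run ends
with a machine-readable ``report.json`` whose fingerprint is a SHA-256 over
the report content, so identical inputs and configuration yield identical
fingerprints.  Externally produced DE tables may replace either raw layer;
without raw matrices the biomarker stage is skipped with a logged reason.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomarkers import evaluate_candidates, records_to_frame
from .containers import DeTable, ExpressionMatrix
from .enrichment import gene_pathway_matrix, quadrant_enrichment, select_core_genes
from .errors import ConfigurationError, PipelineError
from .io import (
    read_de_table,
    read_expression_tsv,
    read_gmt,
    read_groups_tsv,
    read_yaml,
    write_de_table,
    write_json,
)
from .proteome import filter_proteins, impute_knn, normalize_log_median, protein_de
from .quadrants import classify_pairs, match_pairs, select_label_genes, summarize_quadrants
from .transcriptome import de_standin, filter_genes, size_factors

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

# quadrants considered biologically prioritized when deriving default
# biomarker candidates (concordant plus protein-only regulation)
_CANDIDATE_QUADRANTS = ("Q2", "Q3", "Q7", "Q8")


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run."""

    output_dir: str = "quadromics_out"
    counts_path: str | None = None
    abundance_path: str | None = None
    groups_path: str | None = None
    gene_sets_path: str | None = None
    mrna_de_path: str | None = None
    protein_de_path: str | None = None
    mrna_log2fc: float = 0.585
    protein_log2fc: float = 0.263
    alpha: float = 0.05
    p_policy: str = "adjusted"
    knn_k: int = 5
    missing_cutoff: float = 0.5
    enrichment_alpha: float = 0.05
    min_pathways: int = 2
    target_size: int = 20
    top_m: int = 3
    label_top_m: int = 3
    candidate_allowlist: list[str] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.mrna_log2fc <= 0 or self.protein_log2fc <= 0:
            raise ConfigurationError("log2FC cutoffs must be positive")
        for name in ("alpha", "enrichment_alpha"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1)")
        if self.knn_k < 1:
            raise ConfigurationError("knn_k must be >= 1")
        if not 0.0 <= self.missing_cutoff < 1.0:
            raise ConfigurationError("missing_cutoff must be in [0, 1)")
        has_mrna = self.counts_path or self.mrna_de_path
        has_protein = self.abundance_path or self.protein_de_path
        if not (has_mrna and has_protein):
            raise ConfigurationError(
                "each layer needs either a raw matrix or an external DE table"
            )
        if (self.counts_path or self.abundance_path) and not self.groups_path:
            raise ConfigurationError("groups_path required when raw matrices are supplied")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = read_yaml(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _derive_candidates(pairs: pd.DataFrame, label_top_m: int) -> list[str]:
    """Default biomarker candidates: all concordant (Q3/Q7) genes plus the
    top-|protein log2FC| genes of each protein-only quadrant (Q2/Q8)."""
    out: list[str] = []
    for q in _CANDIDATE_QUADRANTS:
        sub = pairs[pairs["quadrant"] == q]
        if q in ("Q3", "Q7"):
            out.extend(sub.index)
        else:
            sub = sub.sort_index()
            ranked = sub.loc[
                sub["protein_log2fc"].abs().sort_values(ascending=False, kind="mergesort").index
            ]
            out.extend(ranked.head(label_top_m).index)
    return sorted(dict.fromkeys(out))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the run report (also written as JSON)."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": {}, "version": __version__}
    stage = "load"
    try:
        groups = read_groups_tsv(config.groups_path) if config.groups_path else None

        # --- mRNA layer ---------------------------------------------------
        stage = "transcriptome_de"
        mrna_scores: ExpressionMatrix | None = None
        if config.counts_path:
            counts = read_expression_tsv(config.counts_path, "mrna", groups=groups)
            filtered, filter_report = filter_genes(counts)
            report["stages"]["gene_filter"] = filter_report.to_dict()
            mrna_de = de_standin(filtered, config.mrna_log2fc, config.alpha)
            sf = size_factors(filtered.values)
            mrna_scores = filtered.with_values(np.log2(filtered.values / sf + 1.0))
        else:
            mrna_de = read_de_table(
                config.mrna_de_path, "mrna", config.mrna_log2fc, config.alpha
            )
        write_de_table(mrna_de, outdir / "mrna_de.tsv")
        report["stages"]["mrna_de"] = {"n_genes": int(len(mrna_de.genes)), **mrna_de.n_by_status()}
        logger.info("mrna_de: %s", report["stages"]["mrna_de"])

        # --- protein layer ------------------------------------------------
        stage = "proteome_de"
        protein_scores: ExpressionMatrix | None = None
        if config.abundance_path:
            abundance = read_expression_tsv(config.abundance_path, "protein", groups=groups)
            retained, prep_report = filter_proteins(abundance, config.missing_cutoff)
            report["stages"]["protein_prep"] = prep_report.to_dict()
            imputed = impute_knn(retained, config.knn_k)
            normalized = normalize_log_median(imputed)
            prot_de = protein_de(
                normalized, config.protein_log2fc, config.alpha, config.p_policy
            )
            protein_scores = normalized
        else:
            prot_de = read_de_table(
                config.protein_de_path,
                "protein",
                config.protein_log2fc,
                config.alpha,
                config.p_policy,
            )
        write_de_table(prot_de, outdir / "protein_de.tsv")
        report["stages"]["protein_de"] = {
            "n_proteins": int(len(prot_de.genes)),
            **prot_de.n_by_status(),
        }
        logger.info("protein_de: %s", report["stages"]["protein_de"])

        # --- integration --------------------------------------------------
        stage = "quadrant_integration"
        pairs = classify_pairs(match_pairs(mrna_de, prot_de))
        labels = select_label_genes(pairs, config.label_top_m)
        pairs_out = pairs.copy()
        pairs_out["label_class"] = labels["label_class"].reindex(pairs.index).fillna("")
        pairs_out.to_csv(outdir / "matched_pairs.tsv", sep="\t")
        summary = summarize_quadrants(pairs)
        write_json(summary.to_dict(), outdir / "quadrant_summary.json")
        report["stages"]["integration"] = {
            "n_pairs": summary.n_total,
            "n_changed": summary.n_changed,
        }
        report["quadrant_summary"] = summary.to_dict()
        logger.info("integration: %s", report["stages"]["integration"])

        # --- enrichment + core genes -------------------------------------
        stage = "enrichment"
        if config.gene_sets_path:
            sets = read_gmt(config.gene_sets_path)
            per_quadrant = quadrant_enrichment(pairs, sets, alpha=config.enrichment_alpha)
            pooled = []
            for quadrant, records in sorted(per_quadrant.items()):
                frame = pd.DataFrame(
                    [
                        {
                            "set_name": r.set_name,
                            "k": r.k,
                            "K": r.K,
                            "n": r.n,
                            "N": r.N,
                            "p": r.p,
                            "adj_p": r.adj_p,
                            "significant": r.significant,
                            "members": ";".join(r.members),
                        }
                        for r in records
                    ]
                )
                frame.to_csv(outdir / f"enrichment_{quadrant}.tsv", sep="\t", index=False)
                for r in records:
                    pooled.append(
                        dataclasses.replace(r, set_name=f"{quadrant}:{r.set_name}")
                    )
            selection = select_core_genes(
                pooled,
                mrna_de,
                min_pathways=config.min_pathways,
                target_size=config.target_size,
                top_m=config.top_m,
                alpha=config.enrichment_alpha,
            )
            core = {
                "hub_genes": list(selection.hub_genes),
                "supplemental_genes": list(selection.supplemental_genes),
                "connectivity": selection.connectivity,
                "n_enriched_genes": selection.n_enriched_genes,
                "selection_rate_pct": selection.selection_rate_pct,
            }
            if selection.selected:
                matrix, density, down_share = gene_pathway_matrix(selection, pooled, mrna_de)
                matrix.to_csv(outdir / "gene_pathway_matrix.tsv", sep="\t", na_rep="NA")
                core["matrix_density"] = density
                core["down_share"] = down_share
            write_json(core, outdir / "core_selection.json")
            report["stages"]["enrichment"] = {
                "n_quadrants_tested": len(per_quadrant),
                "n_significant_records": sum(r.significant for r in pooled),
                "n_core_genes": len(selection.selected),
            }
            report["core_selection"] = core
            logger.info("enrichment: %s", report["stages"]["enrichment"])
        else:
            report["stages"]["enrichment"] = {"skipped": "no gene sets supplied"}

        # --- biomarker evaluation ----------------------------------------
        stage = "biomarker_eval"
        if mrna_scores is None and protein_scores is None:
            reason = "raw matrices unavailable (external DE tables only)"
            logger.info("biomarker stage skipped: %s", reason)
            report["stages"]["biomarkers"] = {"skipped": reason}
        else:
            candidates = list(config.candidate_allowlist) or _derive_candidates(
                pairs, config.label_top_m
            )
            records = evaluate_candidates(candidates, mrna_scores, protein_scores)
            frame = records_to_frame(records)
            frame.to_csv(outdir / "biomarkers.tsv", sep="\t", na_rep="NA")
            report["stages"]["biomarkers"] = {
                "n_candidates": len(records),
                "n_detected_both": sum(
                    r.detected_mrna and r.detected_protein for r in records
                ),
            }
            report["biomarkers"] = frame.reset_index().to_dict(orient="records")
            logger.info("biomarkers: %s", report["stages"]["biomarkers"])
    except Exception as exc:
        write_json(
            {**report, "failed_stage": stage, "error": str(exc)}, outdir / "report.json"
        )
        if isinstance(exc, (PipelineError, ConfigurationError)):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    canonical = json.dumps(report, sort_keys=True, default=str)
    report["fingerprint"] = hashlib.sha256(canonical.encode()).hexdigest()
    write_json(report, outdir / "report.json")
    return report
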