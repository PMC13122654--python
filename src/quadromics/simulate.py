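"""Paired mRNA/protein data generator with planted nine-quadrant structure.

Every downstream stage of the pipeline is testable against this generator:
each gene carries a known quadrant label (Q1–Q9) encoding whether its mRNA
and/or protein level truly differs between the reference (GRA) and treatment
(SUP) arm, and by how much.

Models
------
mRNA counts follow a gamma–Poisson (negative binomial) with a gene-specific
baseline mean drawn log-uniformly and a common dispersion: for mean m and
dispersion a, the variance is m + a·m².  Protein abundances are log-normal
with a common within-group coefficient of variation.  The planted effect is
split symmetrically around the baseline, so the between-group log2 mean ratio
equals the planted log2FC.  Protein missingness is missing-not-at-random:
dropout probability is logistic in (standardized) log2 abundance with the
intercept calibrated so the expected global missing fraction equals
``missing_rate``; lower-abundance entries always drop out more often.

One root seed sequence per dataset; per-gene child streams are spawned
deterministically, so enlarging ``n_genes`` does not perturb the values of
existing genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .containers import GROUP_REFERENCE, GROUP_TREATMENT, ExpressionMatrix
from .errors import ConfigurationError
from .io import write_expression_tsv, write_groups_tsv

__all__ = [
    "QUADRANTS",
    "QUADRANT_SIGNS",
    "DEFAULT_QUADRANT_PROPORTIONS",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_paired_dataset",
    "dropout_probabilities",
    "write_dataset",
]

QUADRANTS = ("Q1", "Q2", "Q3", "Q4", "Q5", "Q6", "Q7", "Q8", "Q9")

# (mRNA direction, protein direction) per quadrant: +1 up, -1 down, 0 unchanged.
QUADRANT_SIGNS: dict[str, tuple[int, int]] = {
    "Q1": (-1, +1),
    "Q2": (0, +1),
    "Q3": (+1, +1),
    "Q4": (-1, 0),
    "Q5": (0, 0),
    "Q6": (+1, 0),
    "Q7": (-1, -1),
    "Q8": (0, -1),
    "Q9": (+1, -1),
}

# Default composition mirrors the observed distribution of 4,080 matched
# gene-protein pairs (Q5 dominant, protein-only quadrants Q8 > Q2 next).
_OBSERVED_PAIRS = {
    "Q1": 7, "Q2": 69, "Q3": 3, "Q4": 10, "Q5": 3812, "Q6": 4, "Q7": 6, "Q8": 165, "Q9": 4,
}
DEFAULT_QUADRANT_PROPORTIONS: dict[str, float] = {
    q: _OBSERVED_PAIRS[q] / sum(_OBSERVED_PAIRS.values()) for q in QUADRANTS
}

# mRNA baseline mean counts are drawn log2-uniformly over this range.
_MRNA_BASELINE_LOG2_RANGE = (4.0, 12.0)
# Slope of the logistic dropout curve in standardized log2-abundance units.
_DROPOUT_SLOPE = 1.5


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of one synthetic paired-omics dataset.

    Defaults emulate the two-arm, n = 6 per group design with a 4,080-pair
    matched universe whose quadrant composition is dominated by unchanged
    (Q5) and protein-only (Q8, Q2) pairs.
    """

    n_per_group: int = 6
    n_genes: int = 4080
    quadrant_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_QUADRANT_PROPORTIONS)
    )
    mrna_effect_log2fc: float = 2.0
    protein_effect_log2fc: float = 1.5
    mrna_dispersion: float = 0.05
    protein_cv: float = 0.15
    baseline_log2_abundance_range: tuple[float, float] = (14.0, 24.0)
    missing_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if self.n_genes < 10:
            raise ConfigurationError("n_genes must be >= 10")
        props = self.quadrant_proportions
        if set(props) - set(QUADRANTS):
            raise ConfigurationError(f"unknown quadrant labels {sorted(set(props) - set(QUADRANTS))}")
        vals = np.array([props.get(q, 0.0) for q in QUADRANTS], dtype=float)
        if (vals < 0).any():
            raise ConfigurationError("quadrant_proportions must be nonnegative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"quadrant_proportions must sum to 1 (got {vals.sum():.12g})")
        if self.mrna_effect_log2fc < 0 or self.protein_effect_log2fc < 0:
            raise ConfigurationError("effect sizes must be nonnegative")
        if self.mrna_dispersion < 0:
            raise ConfigurationError("mrna_dispersion must be nonnegative")
        if self.protein_cv <= 0:
            raise ConfigurationError("protein_cv must be positive")
        lo, hi = self.baseline_log2_abundance_range
        if not lo < hi:
            raise ConfigurationError("baseline_log2_abundance_range must be (low, high) with low < high")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")


@dataclass
class SyntheticDataset:
    """Generated paired dataset plus its ground truth.

    ``truth`` has one row per gene: gene (index), true_quadrant,
    true_mrna_log2fc, true_protein_log2fc.
    """

    mrna_counts: ExpressionMatrix
    protein_abundance: ExpressionMatrix
    truth: pd.DataFrame
    config: SyntheticConfig

    @property
    def groups(self) -> pd.Series:
        return self.mrna_counts.groups


def dropout_probabilities(log2_abundance: np.ndarray, missing_rate: float) -> np.ndarray:
    """Per-entry dropout probability, logistic in standardized log2 abundance.

    The intercept is calibrated so the mean probability equals
    ``missing_rate``; the curve is strictly decreasing in abundance.
    """
    if missing_rate == 0.0:
        return np.zeros_like(log2_abundance, dtype=float)
    z = log2_abundance - log2_abundance.mean()
    sd = log2_abundance.std()
    if sd > 0:
        z = z / sd

    def mean_prob(intercept: float) -> float:
        return float(expit(intercept - _DROPOUT_SLOPE * z).mean()) - missing_rate

    intercept = brentq(mean_prob, -50.0, 50.0, xtol=1e-12)
    return expit(intercept - _DROPOUT_SLOPE * z)


def _sample_labels(n_per_group: int) -> tuple[list[str], pd.Series]:
    samples = [f"{GROUP_REFERENCE}_{i + 1}" for i in range(n_per_group)] + [
        f"{GROUP_TREATMENT}_{i + 1}" for i in range(n_per_group)
    ]
    groups = pd.Series(
        [GROUP_REFERENCE] * n_per_group + [GROUP_TREATMENT] * n_per_group,
        index=samples,
        name="group",
    )
    return samples, groups


def generate_paired_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one reproducible paired mRNA/protein dataset.

    Counts follow the gamma–Poisson model with group mean ratio
    2**true_mrna_log2fc; abundances the log-normal model with group mean
    ratio 2**true_protein_log2fc; missingness is abundance-dependent.
    """
    config.validate()
    n, g = config.n_per_group, config.n_genes
    samples, groups = _sample_labels(n)

    root = np.random.SeedSequence(config.seed)
    ss_truth, ss_mrna, ss_protein, ss_missing = root.spawn(4)

    rng_truth = np.random.default_rng(ss_truth)
    props = np.array([config.quadrant_proportions.get(q, 0.0) for q in QUADRANTS])
    quadrant = rng_truth.choice(QUADRANTS, size=g, p=props)
    sign_m = np.array([QUADRANT_SIGNS[q][0] for q in quadrant], dtype=float)
    sign_p = np.array([QUADRANT_SIGNS[q][1] for q in quadrant], dtype=float)
    true_mrna = sign_m * config.mrna_effect_log2fc
    true_protein = sign_p * config.protein_effect_log2fc
    # Truth labels are defined by the sign/zero pattern of the planted
    # effects, so a zero effect size collapses the affected axis to NS
    # (all-Q5 truth under the full null).
    signs_to_q = {v: k for k, v in QUADRANT_SIGNS.items()}
    quadrant = np.array(
        [signs_to_q[(int(np.sign(m)), int(np.sign(p)))] for m, p in zip(true_mrna, true_protein)]
    )

    gene_symbols = [f"G{i + 1:05d}" for i in range(g)]
    truth = pd.DataFrame(
        {
            "true_quadrant": quadrant,
            "true_mrna_log2fc": true_mrna,
            "true_protein_log2fc": true_protein,
        },
        index=pd.Index(gene_symbols, name="gene"),
    )

    # mRNA counts: per-gene child streams so existing genes are seed-stable.
    counts = np.empty((g, 2 * n), dtype=np.int64)
    lo, hi = _MRNA_BASELINE_LOG2_RANGE
    disp = config.mrna_dispersion
    for i, child in enumerate(ss_mrna.spawn(g)):
        rng = np.random.default_rng(child)
        base = 2.0 ** rng.uniform(lo, hi)
        mean_ref = base * 2.0 ** (-true_mrna[i] / 2.0)
        mean_trt = base * 2.0 ** (+true_mrna[i] / 2.0)
        means = np.concatenate([np.full(n, mean_ref), np.full(n, mean_trt)])
        if disp > 0:
            lam = rng.gamma(shape=1.0 / disp, scale=means * disp)
        else:
            lam = means
        counts[i] = rng.poisson(lam)

    # Protein abundances: log-normal; sigma on log2 scale from the linear CV.
    sigma_log2 = np.sqrt(np.log1p(config.protein_cv**2)) / np.log(2.0)
    blo, bhi = config.baseline_log2_abundance_range
    log2_abund = np.empty((g, 2 * n), dtype=float)
    for i, child in enumerate(ss_protein.spawn(g)):
        rng = np.random.default_rng(child)
        base = rng.uniform(blo, bhi)
        centers = np.concatenate(
            [
                np.full(n, base - true_protein[i] / 2.0),
                np.full(n, base + true_protein[i] / 2.0),
            ]
        )
        log2_abund[i] = rng.normal(centers, sigma_log2)

    abundance = 2.0**log2_abund
    if config.missing_rate > 0:
        rng_missing = np.random.default_rng(ss_missing)
        prob = dropout_probabilities(log2_abund.ravel(), config.missing_rate).reshape(g, 2 * n)
        mask = rng_missing.random((g, 2 * n)) < prob
        # keep the most abundant entry of any fully masked protein observed
        all_masked = mask.all(axis=1)
        if all_masked.any():
            keep = np.argmax(log2_abund[all_masked], axis=1)
            mask[np.flatnonzero(all_masked), keep] = False
        abundance = abundance.copy()
        abundance[mask] = np.nan

    mrna = ExpressionMatrix(
        values=pd.DataFrame(counts.astype(float), index=truth.index.copy(), columns=samples),
        groups=groups,
        layer="mrna",
    )
    protein = ExpressionMatrix(
        values=pd.DataFrame(abundance, index=truth.index.copy(), columns=samples),
        groups=groups,
        layer="protein",
    )
    return SyntheticDataset(mrna_counts=mrna, protein_abundance=protein, truth=truth, config=config)


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> dict[str, dict]:
    """Write counts/abundance/group/truth TSVs; return a file manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "mrna_counts.tsv",
        "abundance": directory / "protein_abundance.tsv",
        "groups": directory / "groups.tsv",
        "truth": directory / "truth.tsv",
    }
    write_expression_tsv(dataset.mrna_counts, paths["counts"])
    write_expression_tsv(dataset.protein_abundance, paths["abundance"])
    write_groups_tsv(dataset.groups, paths["groups"])
    truth = dataset.truth.copy()
    truth.index.name = "gene"
    truth.to_csv(paths["truth"], sep="\t")
    manifest = {
        "counts": {
            "path": str(paths["counts"]),
            "n_rows": int(dataset.mrna_counts.values.shape[0]),
            "n_cols": int(dataset.mrna_counts.values.shape[1]),
        },
        "abundance": {
            "path": str(paths["abundance"]),
            "n_rows": int(dataset.protein_abundance.values.shape[0]),
            "n_cols": int(dataset.protein_abundance.values.shape[1]),
        },
        "groups": {
            "path": str(paths["groups"]),
            "n_rows": int(len(dataset.groups)),
            "n_cols": 2,
        },
        "truth": {
            "path": str(paths["truth"]),
            "n_rows": int(len(dataset.truth)),
            "n_cols": int(dataset.truth.shape[1] + 1),
        },
    }
    return manifest


def null_config(config: SyntheticConfig | None = None, **overrides) -> SyntheticConfig:
    """A copy of `config` with zero planted effects (all genes truly Q5)."""
    base = config or SyntheticConfig()
    props = {q: 0.0 for q in QUADRANTS}
    props["Q5"] = 1.0
    return replace(
        base,
        mrna_effect_log2fc=0.0,
        protein_effect_log2fc=0.0,
        quadrant_proportions=props,
        **overrides,
    )
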