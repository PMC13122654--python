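# quadromics

Nine-quadrant transcriptome–proteome integration for two-group designs:
dual-layer differential expression, concordance classification of matched
gene–protein pairs, quadrant-conditioned over-representation analysis,
two-tier core-gene selection, and cross-omics biomarker evaluation.

## The problem

Bulk RNA-seq and quantitative (e.g. DIA) proteomics of the same tissue
rarely agree: a large share of protein-level changes occur without any
corresponding mRNA change, reflecting post-transcriptional regulation.
`quadromics` quantifies this decoupling for a two-arm comparison (a
reference group `GRA` and a treatment group `SUP`, n per group small, e.g.
6 vs 6). Each gene measured in both layers gets an Up/NS/Down status per
layer, and the pair is placed in the 3 × 3 grid

| | protein Up | protein NS | protein Down |
|---|---|---|---|
| **mRNA Down** | Q1 discordant | Q4 mRNA-only | Q7 concordant down |
| **mRNA NS**   | Q2 protein-only | Q5 unchanged | Q8 protein-only |
| **mRNA Up**   | Q3 concordant up | Q6 mRNA-only | Q9 discordant |

Downstream, each changed quadrant is tested for gene-set over-representation
(one-sided hypergeometric against the matched-pair universe, BH-corrected),
core genes are selected in two tiers (hub genes in ≥ 2 enriched pathways,
then per-pathway top-|log₂FC| supplementation), and candidate biomarkers are
scored by cross-omics Pearson correlation (Fisher-z 95% CI) and per-layer
ROC AUC with DeLong 95% CIs, banded as excellent (≥ 0.9), good ([0.8, 0.9)),
acceptable ([0.7, 0.8)) or poor (< 0.7).

## Statuses and thresholds

- mRNA: counts are filtered (total < 10 removed, `LOC`/`Novel` prefixes
  removed, duplicate symbols collapsed to the highest-mean row), normalized
  by median-of-ratios size factors, and tested per gene with a two-sided
  Welch t on log₂(normalized + 1). A gene is Up if log₂FC > 0.585 (fold
  change > 1.5) with BH-adjusted p < 0.05, Down if log₂FC < −0.585.
  Externally produced DESeq2-style tables can be supplied instead.
- protein: `LOC`-prefixed and > 50%-missing proteins are removed, remaining
  missing values are kNN-imputed (k = 5, neighbors are proteins, distances
  on the log₂ scale), abundances are log₂-transformed and per-sample
  median-centered, and tested with a pooled two-tailed Student t plus BH.
  Cutoff |log₂FC| > 0.263 (fold change > 1.2).

A synthetic paired-omics generator with planted quadrant memberships
(gamma–Poisson counts, log-normal abundances, intensity-dependent missing
values) provides ground truth for every stage.

## Worked example

```python
import numpy as np
from quadromics.simulate import SyntheticConfig, generate_paired_dataset
from quadromics.transcriptome import filter_genes, de_standin, size_factors
from quadromics.proteome import filter_proteins, impute_knn, normalize_log_median, protein_de
from quadromics.quadrants import match_pairs, classify_pairs, summarize_quadrants
from quadromics.biomarkers import evaluate_candidates

config = SyntheticConfig(n_genes=2000, seed=42)
dataset = generate_paired_dataset(config)

filtered, _ = filter_genes(dataset.mrna_counts)
mrna_de = de_standin(filtered)                      # |log2FC| > 0.585, padj < 0.05
retained, _ = filter_proteins(dataset.protein_abundance)
normalized = normalize_log_median(impute_knn(retained, k=5))
prot_de = protein_de(normalized)                    # |log2FC| > 0.263, padj < 0.05

pairs = classify_pairs(match_pairs(mrna_de, prot_de))
s = summarize_quadrants(pairs)
print(f"pairs: {s.n_total}, changed: {s.n_changed} ({s.pct_changed_of_total}%)")
print(f"concordant (Q3+Q7): {s.pct_changed_concordant}%  "
      f"protein-only (Q2+Q8): {s.pct_changed_protein_only}%")

top = pairs[pairs.quadrant == "Q3"].index[:1].tolist()
sf = size_factors(filtered.values)
mrna_scores = filtered.with_values(np.log2(filtered.values / sf + 1.0))
for rec in evaluate_candidates(top, mrna_scores, normalized):
    print(f"{rec.gene_symbol}: r={rec.r:.2f}, AUC mRNA={rec.auc_mrna:.2f} "
          f"({rec.category_mrna}), AUC protein={rec.auc_protein:.2f} ({rec.category_protein})")
```

prints

```
pairs: 1810, changed: 104 (5.75%)
concordant (Q3+Q7): 2.9%  protein-only (Q2+Q8): 85.6%
G00602: r=0.90, AUC mRNA=1.00 (excellent), AUC protein=1.00 (excellent)
```

Of 1,810 matched pairs, 104 (5.75%) changed in at least one layer; 85.6% of
the changed pairs moved only at the protein level — the post-transcriptional
signature the default generator plants — and a planted concordant-up gene
shows a strong cross-omics correlation with perfect group discrimination in
both layers.

The same analysis runs from the shell:

```sh
quadromics simulate --seed 42 --out data/
quadromics run-all --print-config > cfg.yaml   # edit paths, then:
quadromics run-all --config cfg.yaml
```

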