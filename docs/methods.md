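# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions at the edges.

## Differential expression

**mRNA layer.** The pipeline's built-in test is deliberately simple and
desk-verifiable rather than a negative-binomial GLM: counts are normalized
by median-of-ratios size factors (per-gene pseudo-reference = geometric mean
over the gene's nonzero counts; per-sample factor = median ratio over genes
observed in that sample), transformed to y = log₂(normalized + 1), and
compared with a two-sided Welch t-test per gene. log₂FC is defined as
mean(y_SUP) − mean(y_GRA) throughout the package, so positive values mean
higher in the treatment arm. Benjamini–Hochberg adjustment runs across all
tested genes. Where fidelity to a negative-binomial tool is wanted, its
exported table is ingested via `io.read_de_table`; statuses are always
recomputed from the thresholds, never trusted from the file. Cutoffs are
strict inequalities: a gene at exactly |log₂FC| = 0.585 is NS.

Gene filtering precedes testing: total count over all samples < 10 ("fewer
than 10 counts across all samples" is read as a sum over samples, the usual
count pre-filter idiom), case-sensitive `LOC`/`Novel` prefix exclusion, and
duplicate-symbol collapse keeping the highest-mean row (ties go to the
earlier row). The filter report reconciles exactly:
n_out = n_in − low-count − prefix − duplicates.

**Protein layer.** Fixed order: filter → impute → normalize → test.
Filtering removes `LOC`-prefixed proteins and proteins missing in strictly
more than 50% of samples (exactly half is retained). Imputation is kNN over
proteins (rows), the standard proteomics orientation for row-wise
missingness: each missing cell takes the unweighted mean of that sample's
values in the k = 5 nearest proteins, with nan-Euclidean distances scaled
by the number of mutually observed samples and donors restricted to
proteins observed in the target sample; fewer than k eligible donors falls
back to all of them with a logged warning. Distances are computed on the
log₂ scale — observed values are transformed first, imputed, and the final
normalization log₂-transforms and median-centers each sample — because
distances on raw intensities would be dominated by the highest-abundance
proteins. Observed cells pass through bit-identical. The test is a pooled
two-tailed Student t (pooled, not Welch, matching the stated protocol) with
BH correction; cutoff |log₂FC| > 0.263. Zero pooled variance degenerates to
p = 1 for equal means and p = 0 otherwise (logged). The significance policy
defaults to the adjusted p-value; a `raw` policy exists because published
figure captions sometimes threshold on raw p — the discrepancy is surfaced
as an option rather than silently resolved.

## Nine-quadrant integration

The two DE tables are inner-joined on exact gene-symbol equality (symbols
must be unique per layer; upstream filtering guarantees this). The quadrant
is a total function of the status pair — Q1 (Down, Up) … Q9 (Up, Down) with
Q5 = (NS, NS) — so classification is layer-threshold-agnostic. Summaries
report raw counts, raw fractions, and display-rounded percentages
(half-up: two decimals for shares of the total, one decimal for shares of
the changed pairs). Changed pairs are everything outside Q5; regulatory
modes are concordant (Q3+Q7), protein-only (Q2+Q8), mRNA-only (Q4+Q6) and
discordant (Q1+Q9), which partition the changed set.

Plot labeling is hierarchical: all Q3/Q7 pairs are labeled `concordant`;
each other changed quadrant contributes its top 3 pairs, ranked by |mRNA
log₂FC| for Q1/Q4/Q6/Q9 and |protein log₂FC| for Q2/Q8, ties broken by
symbol. Q7 appears in some protocol descriptions of the ranked list as
well; since Q7 is exhaustively labeled anyway, the ranking is irrelevant
there and is ignored.

## Enrichment and core genes

Over-representation uses the one-sided hypergeometric upper tail
P(X ≥ k) — equivalent to Fisher's exact test (greater) and the documented
model of the widely used enrichment packages. Quadrant-conditioned
enrichment uses the full matched-pair universe as the background (so N is
the number of pairs), testing each non-empty quadrant except Q5; q-value
thresholds are treated as BH-adjusted p-values so a single correction
procedure serves the whole package.

Core-gene selection is two-tier: hub genes are members of at least 2
significantly enriched sets (connectivity counted over significant sets
only); if fewer than 20 hubs exist, each significant set contributes its
top 3 members by |log₂FC| that are not yet selected. The gene × pathway
matrix holds the gene's log₂FC where the gene belongs to the pathway;
density (filled fraction) and the down-regulated share of filled cells are
rendered at one decimal. In the integrated pipeline the records pooled over
quadrants feed the selection, ranked on mRNA log₂FC.

## Biomarker evaluation

The cross-omics correlation is the sample Pearson coefficient over the
per-sample (mRNA, protein) values of one gene, with a Fisher-z interval
(atanh transform, SE = 1/√(n−3), back-transformed) and a two-sided t test
on n−2 degrees of freedom. AUC is the Mann–Whitney probability computed
from midranks (ties count ½), with the DeLong placement-component variance
and a normal-theory interval truncated to [0, 1]. Perfect separation gives
SE 0 and a point interval — an honest reflection of the degenerate
resampling variance at small n, not a bug. Scores are never orientation-
flipped: a marker lower in the positive class reports AUC < 0.5 as-is.
Bands are left-closed ([0.9, 1] excellent, [0.8, 0.9) good, [0.7, 0.8)
acceptable, below poor); published band definitions overlap at the
endpoints, so a convention was required and the boundary joins the upper
band. Candidates default to the biologically prioritized quadrants (all of
Q3/Q7 plus the top protein-ranked genes of Q2/Q8); an explicit allowlist
overrides this, standing in for the non-computable "documented functional
relevance" criterion.

## Synthetic data generator

The generator emulates a two-arm design (n = 6 per group by default) over a
matched universe of 4,080 gene–protein pairs whose default quadrant
composition mirrors the observed protein-dominant landscape (Q5 ≈ 93.4%,
Q8 > Q2 ≫ other changed quadrants). Counts are gamma–Poisson with gene
baselines log₂-uniform on (4, 12) and dispersion 0.05; abundances are
log-normal with baseline log₂ intensity uniform on (14, 24) — a typical
DIA intensity range — and within-group CV 0.15. Planted effects default to
2.0 log₂ units (mRNA) and 1.5 (protein), split symmetrically around the
baseline so the group log₂ mean-ratio equals the planted log₂FC; the truth
label is defined by the sign pattern of the planted effects, so zero effect
sizes yield an all-Q5 truth. Missingness is missing-not-at-random: dropout
probability is logistic in standardized log₂ abundance (slope 1.5) with the
intercept solved by root-finding so the expected global missing fraction
equals `missing_rate` (default 0.2). No study reports within-group variance
for either layer, so the dispersion and CV defaults are conventions chosen
to give realistic but comfortably detectable effects.

Seeding uses one root `SeedSequence` per dataset with per-gene child
streams, so enlarging the gene universe leaves existing genes' values
untouched.

What the generator does **not** emulate: raw reads or spectra, library-size
imbalance, batch effects, length/FPKM normalization, correlated gene
modules, or shared mRNA–protein noise. Passing recovery tests therefore
demonstrates that the statistical machinery is correct and calibrated under
the stated generative model, not that the pipeline is robust to every
artifact of real data.

## Problem sizes and numerical conventions

The test suite and the acceptance script run the stochastic experiments at
sizes chosen to make Monte-Carlo error small relative to the asserted
margins while staying quick on a laptop: quadrant recovery pools ≥ 20 seeds
× 240 genes (≈ 2,900 planted non-Q5 genes), the null calibration 20 seeds ×
200 genes, and the Fisher-z coverage check 5,000 simulations per ρ at
n = 12. Percentages are rendered half-up at the displayed precision with
raw fractions retained; fold changes are reported at two significant
figures where rounded display is wanted. Empty quadrants enrich to empty
lists, an all-Q5 pair table summarizes with a degeneracy flag and zero
percentages, and division-by-zero percentage renderings are defined as 0.

## Known limitations

- The Welch-t mRNA stand-in is less powerful than a negative-binomial GLM
  at very low counts and does not shrink dispersions; external DE tables
  are first-class inputs for that reason.
- kNN imputation attenuates planted protein effects when missingness is
  heavy and intensity-dependent, since dropped cells sit in the low tail;
  recovery figures include this effect.
- DeLong intervals at n = 6 + 6 are wide and collapse to a point under
  perfect separation; they should be read as descriptive at this scale.
- The package never queries annotation services; gene sets are user-supplied
  GMT and symbols are the only join key.
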