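# Methods

`coexqc` builds cell-type-specific gene co-expression networks from
multi-study RNA-seq count collections under a grid of processing
workflows, scores each network with annotation-enrichment quality
measures, and models which processing choices drive quality. This note
records the models, the defaults and why they were chosen, and what the
synthetic experiments do and do not establish.

## Pipeline model

A workflow is a triple (normalization, batch correction, correlation).
For one dataset it runs: between-sample normalization → log2 with a
data-driven pseudocount → batch correction on the log scale → gene
filtering → gene-gene correlation → per-gene top-K neighbor sets
(`set_X`, K = 100 by default, self excluded). The full benchmark design
crosses 6 normalizations with 4 correction options (none, linear
removal, ComBat, ComBat-seq) plus ComBat-seq applied to raw counts, and
2 correlation measures: 50 workflows. ComBat-seq operates on the count
scale and is outside this package's scope; its workflows are enumerable
for design arithmetic but not executable, leaving 6 × 3 × 2 = 36
executable workflows.

### Normalization

* **CPM** — reads per million of the sample total.
* **UQ / Med** — scaling by the 75th percentile / median of the
  sample's non-zero counts. Quantiles use linear interpolation between
  order statistics (NumPy's default, R's type 7); the convention is a
  package decision, made once for reproducibility.
* **Quantile** — every sample forced to the across-sample mean empirical
  distribution; tied ranks receive the mean of the values they replace.
  This tie rule keeps the output deterministic; it differs from
  interpolation-based implementations only for ≥3-way ties.
* **TMM** — the edgeR-default algorithm: reference sample chosen by the
  library-scaled 75th percentile closest to the mean; gene-wise log
  ratios trimmed 30% two-sided (and average abundances 5%), averaged
  with inverse asymptotic binomial-variance weights; factors rescaled to
  geometric mean 1 and applied on top of CPM. Genes under 1 CPM in every
  sample are removed first. The implementation reproduces
  `edgeR::calcNormFactors` to 1e-8 on test fixtures.
* **Rlog (simplified)** — median-of-ratios size factors, then per-gene
  shrinkage of `log2(count/s + 0.5)` toward the gene's across-sample
  mean with weight `m/(m + c)`, `m` the gene's mean normalized count and
  `c = 10`. A full regularized log estimates per-gene NB dispersions;
  this version keeps its qualitative behavior — low-count genes pulled
  toward their average, high-count genes ≈ plain log — with one
  interpretable constant. Its output is already log-scale and skips the
  pseudocount transform.

The pseudocount for the log transform is the 1st percentile of the
pooled non-zero values of the whole normalized matrix (one value per
dataset, not per sample), recorded in the matrix provenance.

### Batch correction

Batches are studies: the unit of shared technical variation. Both
correctors protect a biology covariate (cell type / tissue):

* **Linear removal** — per-gene OLS on biology indicators plus
  sum-to-zero batch contrasts; the fitted batch component is subtracted,
  so the grand level and biology group means are preserved exactly in
  balanced designs. Matches `limma::removeBatchEffect` to 1e-10 in
  tests.
* **ComBat** — parametric empirical Bayes: per-gene standardization,
  per-batch location (γ) and scale (δ²) estimates shrunk toward
  moment-matched normal and inverse-gamma priors via the standard
  fixed-point iteration, stopped at max absolute change < 1e-6 (cap 500
  iterations; the reference implementation uses a relative criterion —
  the difference is below 1e-3 on test fixtures, where the output
  matches `sva::ComBat`).

Correction is applied per *confounding block* — a connected component of
the bipartite batch–biology graph — because only within such a block can
batch be distinguished from biology. Single-batch blocks pass through
unchanged and are merged back. Within a connected block complete
batch–biology aliasing cannot arise for the location model, but the
block-level fitters still guard against rank deficiency and skip with a
warning rather than silently removing biology.

### Gene filtering and networks

Genes are filtered on raw counts: removed if fewer than 10 reads in
>90% of samples, or fewer than 10 reads in >80% of samples and never
≥50 reads, or zero variance. The zero-variance check is repeated on the
processed matrix, since normalization can flatten a gene. Correlation is
Pearson or Spearman (mid-ranks for ties); top-K ties are broken by
descending correlation then ascending gene identifier, making networks
bit-reproducible.

### Quality measures and the Quality score

For each annotation domain (GO MF/BP/CC and promoter TFBS motifs),
*Enrichment* is the fraction of genes whose `set_X` contains at least
one significantly enriched term, and *Accuracy* the fraction whose own
annotations intersect those enriched terms — so Accuracy ≤ Enrichment by
construction. Enrichment per term is the one-sided hypergeometric tail
over the network's gene universe with Benjamini–Hochberg control across
the domain's tested terms per `set_X` (α = 0.05). Terms with fewer than
5 genes in the universe, or more than half of it, are not tested. The
Accuracy denominator is all network genes; a conditional variant
(denominator = genes with any enrichment) is available as an argument
but is not the default. Hypergeometric and BH-FDR choices are the field
defaults; the test statistic and correction method are configurable
decisions, not estimates.

Across a collection of networks the eight measures are standardized and
the first principal component of their correlation matrix, sign-oriented
to correlate positively with the measure mean and min–max rescaled to
[0, 1], is the scalar **Quality**. Quality is collection-relative:
0 is the worst network of the analyzed set, 1 the best. Scoring an
out-of-collection network projects its standardized measures onto the
stored loadings and clamps to [0, 1]; the clamp is an extension beyond
the original scheme and is flagged here deliberately.

### Workflow analysis

Quality is modeled by OLS on log10 sample count, log10 batch count,
species, and 0/1 dummies for normalization (baseline Quantile),
correction (baseline none) and correlation (baseline Pearson); t and
two-sided p values use df = n − p. A coefficient β converts to the
equivalent percent change in sample count as `100·(10^(β/β_n) − 1)`,
β_n the log10-sample-count slope — the processing choice buys the same
Quality as that many percent more samples. Cross-validation refits the
model over leave-one-fold-out partitions of *datasets* (never network
rows). Workflow ranking uses mean Quality and counts datasets where a
workflow beats that dataset's mean Quality across workflows (the
"above-average" baseline is per-dataset, a package decision). Paired
default-vs-optimized comparisons use one-sided paired t-tests per
measure, unadjusted across the eight measures.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
NB counts (variance μ + φμ², one global φ, default 0.1) around
log-normal library factors; per-gene log2 intercepts N(5, 2²); latent
module activities a ~ N(0,1) shared within modules with loading L
(default 1.0; base residual variance 0.25 on log2 scale puts
within-module correlation at L²/(L²+0.25) = 0.8); per-batch per-gene
location shifts N(0, batch_loc_sd²) and per-batch variance-scale factors
exp(δ), δ ~ N(0, batch_scale_sd²); round-robin (balanced) batch
assignment; one biology per dataset, with a confounded multi-biology
mode for exercising the partitioner. Annotation sets give each module
one term per domain populated at a true-positive rate (default 0.8)
plus background terms populated at a false-positive rate (default 0.01).

Two opt-in contamination knobs exist for robustness experiments, both
off by default: a fixed count of artifact samples carrying extra
per-gene log2 noise (fixed count, not a fixed fraction — emulating the
rare aberrant libraries of real compendia, whose influence is diluted in
larger datasets), and heavy-tailed module activities (variance-
standardized Student-t, df > 2) emulating burst-like activation where
rare extreme samples carry real signal.

What the generator does **not** emulate: gene-length/GC bias, realistic
annotation incompleteness and redundancy (GO term nesting), ontology
structure, heterogeneous per-study batch mechanisms, count-level batch
interactions, or multi-condition designs. Passing tests therefore show
that the pipeline recovers the structure this model encodes — not that
any workflow is optimal on real compendia.

## Experiment designs behind the headline checks

* **Correction benefit** (10 replicates): 12 datasets of 2,000 genes,
  100–300 samples, 5–10 batches (batch counts deliberately decorrelated
  from sample counts), batch shift sd 1.0; UQ + Pearson with and without
  ComBat, scored as one collection per replicate. Corrected mean Quality
  must win in ≥8/10 replicates.
* **Sample-count slope** (10 replicates): 12 datasets spanning 20–400
  samples with 2–12 batches varied within sample tiers, module loading
  0.5. At the default loading 1.0 the enrichment measures saturate by
  ~100 samples and the slope vanishes; a weaker, more realistic signal
  keeps Quality rising across the range. β_n > 0 and positive correction
  coefficients are required in ≥8/10 replicates.
* **Batch-count trend**: across 1–5 batches at fixed n = 120, the
  ComBat-minus-none Quality gain rises with batch count (Spearman > 0).
  *Known divergence*: beyond ~5 batches at fixed n this homogeneous
  batch model's spurious correlation decays like 1/batches, so the gain
  plateaus and then declines — unlike real compendia, where datasets
  with many studies keep benefiting, presumably because real technical
  heterogeneity grows with the number of studies. The test covers the
  transition regime the model does reproduce.
* **Correlation crossover** (10 replicates, sign criterion ≥8/10 per
  band): with heavy-tailed activities (t3) and 2 artifact samples per
  dataset (noise sd 1.6 log2 units), Spearman wins below 30 samples and
  Pearson in the 30–100 band. The mechanism: rank correlation bounds the
  influence of artifact samples (decisive when one of 20 samples is
  corrupted) but compresses informative extreme activity values, a
  constant handicap that dominates once artifact influence is diluted.
  Parameters were calibrated by pilot simulation of the latent model and
  then frozen.
* **Neighbor-count robustness**: measures from the top 50/100/200
  neighbors of the same correlation matrices, over a 20-network
  collection; concatenated measure vectors must correlate ≥ 0.8.

## Numerical choices and degenerate inputs

Quantile conventions are linear-interpolation throughout. UQ/Med reject
all-zero samples by name; TMM rejects empty post-filter matrices; the
log transform rejects all-zero matrices and double application. ComBat
rejects single-sample batches by name and reports non-convergence with
iteration diagnostics. The Quality PCA rejects collections under 3
networks and names constant measure columns. Degenerate paired
comparisons (zero-variance differences) report t = 0, p = 1 for
identical workflows and the closed-form limit t = ±∞ otherwise.
Correlation requires ≥3 samples and pre-filtered constant genes.

## Problem sizes

Default test-suite experiments use 400–2,000 genes and 20–400 samples —
sizes chosen so the full suite, including the replicate experiments,
runs in minutes on one CPU while every statistical claim is still
testable at conventional power. The pipeline itself is vectorized
(lookup-table hypergeometric tails, vectorized BH, dense BLAS
correlation) and handles genome-scale gene counts in seconds per
network.
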