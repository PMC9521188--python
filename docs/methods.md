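# Methods

`ptiseq` implements the downstream analysis of a baseline-anchored
immune-elicitation time course: leaf disks treated with the flagellin
epitope flg22 and sampled at 0, 0.5, 1, 3, 6 and 12 h after treatment,
three biological replicates per time point, quantified as gene-level read
counts. The package covers differential-expression calling against the
0 h control, trajectory clustering of the responsive genes, promoter
cis-element scanning, and per-cluster over-representation statistics. A
first-class synthetic-data generator with recorded ground truth makes
every stage testable without external downloads.

## Differential expression

**Normalization.** Between-sample scaling uses the trimmed mean of
M-values (TMM): the reference sample is the one whose upper quartile of
count/library-size is closest to the mean upper quartile; per sample, the
weighted mean of log2 ratios is taken after trimming 30% of the M-values
and 5% of the A-values on each side, with asymptotic (delta-method)
precision weights; factors are geometric-mean centered so they multiply
to 1. The implementation reproduces edgeR's `calcNormFactors(method="TMM")`
to 1e-12 on integer count fixtures.

**Test.** Each non-baseline time point is contrasted against 0 h with a
negative-binomial likelihood-ratio test. The NB is parameterized as
Var(Y) = mu + phi mu^2. Per-gene dispersion is estimated by method of
moments from within-group residuals on effective-size-factor-normalized
counts, then shrunk 50/50 toward a mean-binned trend (20 quantile bins on
the gene mean). Bin *means*, not medians, form the trend: the per-gene
moment estimator is strongly right-skewed at 2 residual degrees of
freedom per group, and a median trend biases the dispersion low enough to
visibly inflate the type-I error. Group means are fitted by Newton
iteration on the log scale with offsets log(library size x TMM factor),
and the p-value comes from the chi-square(1) tail of the likelihood
ratio. With n = 3 vs 3 the plug-in dispersion makes the test mildly
liberal; simulations at mu = 100, phi = 0.1 put the raw-p type-I rate
near 0.06 at alpha = 0.05, within the calibration band the test suite
enforces. An omnibus variant (any change across time points, chi-square
with T-1 df) is provided for exploratory filtering. Genes with total
count < 10 across all samples are never tested (reported as NA).

This NB test is a deliberately transparent, deterministic desk-scale
test; it does not promise parity with edgeR's quasi-likelihood F-test.
For re-running the published filter on a precomputed statistics table,
`read_stats_table` ingests (gene, time point, log2FC, p[, FDR]) and
applies BH per contrast when FDR is absent.

**Multiple testing.** Benjamini-Hochberg step-up, applied within each
contrast (DEG selection is per time point). The implementation is checked
exactly (1e-12) against a definitional oracle and against statsmodels.

**DEG filter.** A gene is up-regulated at t iff log2FC > 1 AND FDR < 0.01
AND p < 0.01 (all strict; "more than 2-fold" excludes exactly 2-fold),
down-regulated symmetrically. Both p and FDR thresholds are applied
jointly even though the FDR cut usually implies the p cut. The union DEG
set counts a gene once however many time points it passes.

## Trajectory clustering

Profiles fed to clustering are per-time-point means over replicates of
log2(normalized count + 1). The log transform matters: on the linear
scale, down-regulation is compressed toward zero and the z-profile of a
repressed gene is dominated by its baseline value, which breaks direction
classification downstream. Each profile is standardized to mean 0 /
sample sd 1 (n-1 denominator); zero-variance rows are excluded and
reported.

k-means uses Euclidean distance with careful seeding (k-means++), 25
restarts by default, keeping the solution with the lowest within-cluster
sum of squares; the backend is scikit-learn, which never returns empty
clusters. Clusters are relabeled deterministically for presentation:
down-regulated clusters first, ordered by trough time, then up-regulated
clusters by peak time, with onset time (first half-maximal deviation) as
the tie-break. Direction is judged relative to the centroid's *baseline*
(0 h) value — down iff the excursion below baseline exceeds the excursion
above it, ties resolving to up. Judging against the centroid mean instead
(|min| vs |max|) mislabels noisy dips whose baseline z dominates; the
baseline-relative rule agrees with the mean-relative rule on clean
archetypes and fixes the noisy case.

**Gap statistic.** For each candidate k, gap(k) = E*[log W_k] - log W_k
against B reference datasets drawn uniformly over the per-feature data
ranges (the simpler of the two published reference variants; the
PCA-rotated variant is not implemented). s_k = sd_B(log W*_k) sqrt(1+1/B),
and the selected k is the smallest with gap(k) >= gap(k+1) - s_{k+1}.
Defaults are B = 50 for interactive use; the automated benchmark uses
B = 20, k in 2..13 and 4 reference restarts, which keeps the full
20-seed selection study under two minutes at n = 2,000 while leaving the
selection rule B-aware through s_k.

**Markers.** Within each requested cluster (default: the up-regulated
ones), genes correlating with the centroid at >= 0.8 are ranked by
maximal |log2FC| over the contrasts and the top two are reported; a
cluster with no gene above the floor falls back to pure correlation
ranking and is flagged.

## Promoters and cis-elements

The promoter is the 1-kb window immediately 5' of the translation start:
plus strand [start-1000, start-1], minus strand [end+1, end+1000]
reverse-complemented, 1-based inclusive coordinates throughout (BED
output converts to 0-based half-open at the boundary only). The
translation start is the 5'-most CDS coordinate of the transcript with
the longest total CDS. Windows clipped at a contig edge carry a
`truncated` flag. Upstream gene bodies are not masked.

Motifs are degenerate consensus strings over A/C/G/T/N with alternation
groups, e.g. the DRE/CRT element `(A/G)CCGAC`. The shipped dictionary
holds the 15 elements used in the flg22 promoter analysis (GCC-box,
DRE/CRT, DRE-like for AP2/ERF; Myc-related for MYC/NAC; G-box,
G-box-like, ABRE-like, ACTCAT, TGA for bZIP; AtMyb1-4 for MYB; W-box for
WRKY; CG-1 for CAMTA). The W-box, printed ambiguously as "TTGAC/T", is
read as the canonical TTGAC(C/T) (TTGACY); the alternative TTGA(C/T)
reading is available by editing the motif TSV. AtMyb1 and AtMyb2 share an
identical printed consensus and are carried verbatim as two entries.
Scanning slides the pattern over the sequence (overlaps allowed); an N in
the scanned sequence matches nothing. Default strand mode is both
strands, with reverse-strand hits mapped back to sense-promoter
coordinates; single-strand mode is a flag. Presence is deduplicated per
gene x motif. The scanner is verified against an enumeration oracle
(expand all matching words, substring-search each) on random sequences.

## Over-representation

For a cluster of n genes from a universe of N containing K genes in a
category, the reported p is the hypergeometric upper tail P(X >= k),
computed via scipy's log-space survival function and verified
exhaustively (N <= 30) against integer-arithmetic pmf summation at 1e-12.
Tests are one-sided (over-representation) only. The default universe is
every gene in the annotation input (genome-wide background), configurable
to DEGs-only; the choice is recorded in the run manifest. Annotated genes
outside the universe are dropped from their category with a logged count.
Heatmap matrices report -log10 of the raw p (the conventional display);
BH-adjusted q-values within each category class are carried in the
results table. No GO-graph ancestor propagation is performed; the map is
taken as-is.

## Synthetic data

The generator emulates the statistical structure of the study, not its
biology in detail:

- **Counts.** NB draws with mean mu_g 2^{delta_{a(g),t}} s_j. Baseline
  means are log-normal (median 80, log-sd 1); dispersions follow a trend
  phi = 0.04 + 2/mu with log-normal scatter (typical bulk RNA-seq
  magnitudes); library-size factors s_j are log-uniform in [0.7, 1.4] so
  normalization is non-trivial. Ten trajectory archetypes (4 down with
  troughs at 1, 3, 6, 12 h — one recovering by 12 h — and 6 up with peaks
  at 0.5, 1, 3, 6, 6+12, 12 h) mirror the published cluster shapes;
  archetype 0 is null. All offsets are anchored to 0 at baseline.
- **Genomes.** Uppercase-ACGT contigs with one single-CDS gene per
  non-overlapping slot and random strand. Motifs are planted into the
  sense promoter with probability o/(1+o) per archetype-specific odds o
  (infinite odds force planting), at non-overlapping random positions;
  minus-strand promoters are written reverse-complemented into the
  genome so strand-aware extraction must recover the planted word. The
  truth manifest records every site.
- **Annotations.** Background gene-term assignment is independent
  Bernoulli at rate terms_per_gene/n_terms; each archetype's designated
  terms are assigned to its members at fold_enrichment x background.

What the generator does *not* model: read-level noise, isoform structure,
correlated genes, batch effects, and diurnal/circadian drift — the last
being explicitly confounded with treatment in this design, since every
contrast is against the single 0 h baseline. Passing recovery tests on
this generator therefore demonstrates correctness of the computations,
not robustness to those real-data complications.

All stochastic stages derive their seeds from one run seed via a
stage-name hash, so stages are independently reproducible and a full
pipeline run is byte-deterministic (manifest timestamps aside).

## Problem sizes in the automated checks

The test suite and `scripts/acceptance.py` use desk-scale sizes chosen to
make the statistical assertions sharp yet quick: 5,000 genes for test
calibration (type-I band 0.03-0.08 at alpha 0.05), 1,000 planted 4-fold
genes for power (>= 0.8 at the triple filter), 2,000 trajectories for
cluster recovery (ARI >= 0.9) and gap-statistic selection (k in {9,10,11}
in >= 16/20 seeds), a 1,000-gene end-to-end bundle for the pipeline
metrics. Larger sizes change none of the qualitative conclusions.

## Known limitations

- The NB test is mildly liberal at n = 3 per group and is not an edgeR
  replacement; published DEG lists should be reproduced through the
  precomputed-statistics reader.
- The gap statistic's uniform reference over feature ranges is sensitive
  to outlying profiles; the PCA-rotated reference is not available.
- k-means with Euclidean distance on z-scores cannot represent
  non-convex or unequal-variance cluster shapes.
- Enrichment p-values are raw hypergeometric tails; with the genome-wide
  universe they inherit its composition biases, and no gene-length or
  expression-level bias correction is attempted.
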