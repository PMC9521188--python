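# ptiseq

Time-course transcriptome analysis of pattern-triggered immunity (PTI).

When a plant perceives a microbe-associated molecular pattern such as the
flagellin peptide flg22, thousands of genes respond over the following
hours. `ptiseq` implements the downstream analysis of such an experiment
— gene-level counts from a baseline-anchored time course (0, 0.5, 1, 3,
6, 12 h after treatment, replicated) — as a tested, reusable library and
CLI:

1. **DEG calling** — TMM normalization, a negative-binomial
   likelihood-ratio test of each time point against the 0 h control,
   Benjamini–Hochberg adjustment per contrast, and the joint filter
   |log2FC| > 1 ∧ FDR < 0.01 ∧ p < 0.01.
2. **Trajectory clustering** — per-gene z-scoring of replicate-averaged
   log expression profiles, Euclidean k-means (k = 10 by default, 25
   restarts), gap-statistic assessment of the cluster number, and
   marker-gene selection per cluster.
3. **Promoter cis-elements** — strand-aware extraction of the 1-kb window
   upstream of each translation start from FASTA + GFF3, scanned with a
   dictionary of 15 degenerate consensus elements (W-box, G-box,
   ABRE-like, GCC-box, DRE/CRT, CG-1, …).
4. **Over-representation** — upper-tail hypergeometric tests of GO terms,
   TF families and motif presence within each cluster, with
   −log10(p) heatmap matrices.
5. **Synthetic data** — NB count matrices with 10 planted trajectory
   archetypes, random genomes with archetype-dependent planted promoter
   motifs, and annotation maps with planted enriched terms, all recorded
   in a truth manifest for recovery scoring.

The statistics at the core: for a cluster of *n* genes drawn from a
universe of *N* of which *K* carry a category, enrichment is
P(X ≥ k) = Σ_{x=k}^{min(n,K)} C(K,x)·C(N−K,n−x)/C(N,n); the gap statistic
is gap(k) = E*[log W_k] − log W_k against B uniform reference draws, with
k selected as the smallest satisfying gap(k) ≥ gap(k+1) − s_{k+1}.

## Worked example

```python
import ptiseq as p

# a synthetic experiment with known planted structure
design = p.TimeCourseDesign(n_genes=2000)
truth = p.default_truth(design, seed=42, frac_null=0.3)
counts, manifest = p.simulate_counts(design, truth)

# 1) differential expression vs the 0 h baseline
model = p.DifferentialExpression(counts)
res = model.fit()
degs = res.filter_degs()          # |log2FC|>1, FDR<0.01, p<0.01
print(degs.counts())

# 2) cluster the DEG trajectories
prof = p.replicate_mean_profiles(counts, model.factors).loc[degs.union]
traj = p.zscale(prof)
results = p.TrajectoryKMeans(traj, k=10, seed=1, n_restarts=25).fit()
print(results.summary())
```

```
             0.5    1.0    3.0    6.0   12.0   union
direction
up         195.0  336.0  460.0  432.0  341.0     NaN
down       107.0  299.0  435.0  411.0  234.0     NaN
total      302.0  635.0  895.0  843.0  575.0  1357.0
        direction  extremum_h  size
cluster
1            down         1.0   131
2            down         3.0   137
3            down         6.0   135
4            down        12.0   124
5              up         0.5   116
6              up         1.0   145
7              up         3.0   156
8              up         6.0   140
9              up        12.0   136
10             up        12.0   137
```

The first table is the per-time-point DEG summary: of 2,000 simulated
genes (30% null), 1,357 distinct genes pass the filter at some time
point, with the response peaking at 3–6 h. The second table shows the
recovered cluster structure: four down-regulated clusters ordered by
trough time and six up-regulated clusters ordered by peak time — the
planted archetype layout. From here,
`p.ClusterEnrichment(results, annotation_map).fit()` scores per-cluster
over-representation, and `results.select_markers(res.contrasts)` picks
two centroid-faithful, strongly induced marker genes per up-regulated
cluster.

The same pipeline runs from the shell:

```sh
ptiseq simulate --n-genes 2000 --seed 42 --out-dir sim/
ptiseq run --config run.yaml        # deg -> cluster -> enrich, with manifest
ptiseq promoters --fasta genome.fa --gff genes.gff3 --out-prefix proms
ptiseq scan --promoters proms.fasta --out-prefix motifs
```

Published DEG tables can be re-filtered without re-testing via
`ptiseq deg-filter --from-stats --stats stats.tsv --out-prefix degs`,
where `stats.tsv` has columns gene_id, timepoint_h, log2FC, p (FDR is
BH-filled per contrast when absent).

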