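"""Synthetic-data generator: seeded determinism, NB moment recovery,
motif planting, annotation planting."""

import numpy as np
import pandas as pd
import pytest

from ptiseq.deg import adjust_bh
from ptiseq.enrich import AnnotationMap, ClusterEnrichment
from ptiseq.motifs import load_motifs, presence_table, scan_promoter
from ptiseq.promoters import extract_promoters
from ptiseq.simulate import (
    DEFAULT_ARCHETYPE_DELTAS,
    PlantedTruth,
    TimeCourseDesign,
    default_truth,
    simulate_annotations,
    simulate_counts,
    simulate_genome,
    simulate_trajectories,
)


class TestDesignAndTruth:
    def test_design_invariants(self):
        with pytest.raises(ValueError):
            TimeCourseDesign(timepoints_h=(0, 1, 1))
        with pytest.raises(ValueError):
            TimeCourseDesign(timepoints_h=(1, 2, 3))
        with pytest.raises(ValueError):
            TimeCourseDesign(replicates_per_timepoint=1)

    def test_archetype_directions(self):
        d = DEFAULT_ARCHETYPE_DELTAS
        assert np.all(d[:, 0] == 0)
        for a in range(1, 5):
            assert d[a].min() < 0 and d[a].max() <= 0
        for a in range(5, 11):
            assert d[a].max() > 0 and d[a].min() >= 0

    def test_nonpositive_parameters_rejected_with_gene_index(self):
        with pytest.raises(ValueError, match="gene index 1"):
            PlantedTruth(mu=[10.0, -1.0], phi=[0.1, 0.1], archetype=[0, 0])
        with pytest.raises(ValueError, match="phi"):
            PlantedTruth(mu=[10.0, 10.0], phi=[0.1, 0.0], archetype=[0, 0])


class TestCounts:
    def test_seeded_determinism(self, design_small, truth_small):
        a, _ = simulate_counts(design_small, truth_small)
        b, _ = simulate_counts(design_small, truth_small)
        assert a.counts.equals(b.counts)

    def test_mean_recovery_null_low_dispersion(self):
        # all delta = 0, phi ~ 0, mu = 100: per-sample mean across 1000
        # genes ~ 100 * s_j within 3 SE
        design = TimeCourseDesign(n_genes=1000)
        truth = PlantedTruth(
            mu=np.full(1000, 100.0), phi=np.full(1000, 1e-8),
            archetype=np.zeros(1000, int), seed=5,
        )
        cm, manifest = simulate_counts(design, truth)
        s = pd.Series(manifest["library_factors"])
        for col in cm.counts.columns:
            expect = 100.0 * s[col]
            se = np.sqrt(expect / 1000)  # Poisson-like at phi ~ 0
            assert abs(cm.counts[col].mean() - expect) < 3 * se + 0.5

    def test_fold_change_moment_recovery(self):
        # archetype with delta = 2 at 3 h -> mean at 3 h ~ 4x baseline
        tp = (0.0, 0.5, 1.0, 3.0, 6.0, 12.0)
        deltas = np.array([[0.0] * 6, [0, 0, 0, 2.0, 0, 0]])
        truth = PlantedTruth(
            mu=np.full(1000, 100.0), phi=np.full(1000, 0.05),
            archetype=np.ones(1000, int), deltas=deltas, seed=6,
        )
        design = TimeCourseDesign(n_genes=1000, timepoints_h=tp)
        cm, manifest = simulate_counts(design, truth)
        s = pd.Series(manifest["library_factors"])
        norm = cm.counts.div(s, axis=1)
        m3 = norm.loc[:, cm.samples["timepoint_h"] == 3.0].mean(axis=1)
        m0 = norm.loc[:, cm.samples["timepoint_h"] == 0.0].mean(axis=1)
        assert (m3.mean() / m0.mean()) == pytest.approx(4.0, rel=0.05)

    def test_nb_variance_matches_parameterization(self):
        # empirical mean/var of NB draws match (mu, mu + phi mu^2) at n=1000
        design = TimeCourseDesign(
            n_genes=1, timepoints_h=(0.0, 1.0), replicates_per_timepoint=500,
        )
        truth = PlantedTruth(mu=[200.0], phi=[0.15], archetype=[0], deltas=np.zeros((1, 2)), seed=7)
        cm, manifest = simulate_counts(design, truth)
        s = pd.Series(manifest["library_factors"])
        x = (cm.counts.iloc[0] / s).to_numpy()
        mu, phi = 200.0, 0.15
        var = mu + phi * mu**2
        assert x.mean() == pytest.approx(mu, abs=3 * np.sqrt(var / 1000))
        assert x.var(ddof=1) == pytest.approx(var, rel=0.25)

    def test_dimension_mismatch_rejected(self, truth_small):
        with pytest.raises(ValueError):
            simulate_counts(TimeCourseDesign(n_genes=10), truth_small)


class TestGenome:
    def test_forced_planting_every_promoter_has_site(self):
        design = TimeCourseDesign(n_genes=40)
        truth = default_truth(design, seed=2)
        truth.motif_odds = {a: {"W-box": np.inf} for a in range(11)}
        motifs = load_motifs()
        genome, gff, manifest = simulate_genome(40, 80000, 1000, motifs, truth)
        assert len(manifest["planted_motifs"]) == 40
        wbox = next(m for m in motifs if m.name == "W-box")
        proms = _extract(genome, gff, tmpdirless=True)
        for gid, p in proms.items():
            assert scan_promoter(p.sequence, wbox, "given"), gid

    def test_zero_odds_background_rate(self):
        design = TimeCourseDesign(n_genes=100)
        truth = default_truth(design, seed=3)
        truth.motif_odds = {}
        motifs = load_motifs()
        genome, gff, manifest = simulate_genome(100, 100000, 1000, motifs, truth)
        assert manifest["planted_motifs"] == []
        proms = _extract(genome, gff)
        wbox = next(m for m in motifs if m.name == "W-box")
        L, w, q = 1000, 6, 2 / 4**6
        expect = 1 - (1 - q) ** (2 * (L - w + 1))
        table = presence_table(proms, [wbox], "both")
        freq = table["W-box"].mean()
        se = np.sqrt(expect * (1 - expect) / 100)
        assert abs(freq - expect) < 4 * se

    def test_planted_sites_recovered_after_strand_aware_extraction(self):
        design = TimeCourseDesign(n_genes=60)
        truth = default_truth(design, seed=4)
        motifs = load_motifs()
        genome, gff, manifest = simulate_genome(60, 100000, 1000, motifs, truth)
        proms = _extract(genome, gff)
        assert len(manifest["planted_motifs"]) > 0
        for rec in manifest["planted_motifs"]:
            seq = proms[rec["gene_id"]].sequence
            site = rec["site"]
            pos = rec["position"]
            assert seq[pos - 1 : pos - 1 + len(site)] == site  # sense-strand recovery

    def test_minus_strand_site_absent_from_raw_genome_window(self):
        design = TimeCourseDesign(n_genes=60)
        truth = default_truth(design, seed=4)
        truth.motif_odds = {a: {"GCC-box": np.inf} for a in range(11)}  # AGCCGCC, not palindromic
        motifs = load_motifs()
        genome, gff, manifest = simulate_genome(60, 100000, 1000, motifs, truth)
        proms = _extract(genome, gff)
        minus = [g for g, p in proms.items() if p.strand == "-"]
        assert minus, "expected some minus-strand genes"
        checked = 0
        for rec in manifest["planted_motifs"]:
            p = proms.get(rec["gene_id"])
            if p is None or p.strand != "-":
                continue
            raw = genome[p.contig][p.start - 1 : p.end]
            assert p.sequence != raw  # strand-aware revcomp needed
            assert rec["site"] in p.sequence
            checked += 1
        assert checked > 0

    def test_contig_too_short_rejected(self, truth_small):
        with pytest.raises(ValueError, match="too short"):
            simulate_genome(10, 500, 1000, load_motifs(), truth_small)


def _extract(genome, gff, tmpdirless=False):
    import tempfile, os

    with tempfile.TemporaryDirectory() as d:
        fa = os.path.join(d, "g.fa")
        gf = os.path.join(d, "g.gff3")
        with open(fa, "w") as fh:
            for c, s in genome.items():
                fh.write(f">{c}\n{s}\n")
        open(gf, "w").write(gff)
        return extract_promoters(fa, gf, 1000)


class TestAnnotations:
    def _arch(self, n, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n)]
        return genes, dict(zip(genes, rng.integers(0, 11, n)))

    def test_null_fold_gives_uniform_pvalues(self):
        genes, arch = self._arch(2000, seed=1)
        ann, _ = simulate_annotations(genes, arch, n_terms=200, fold_enrichment=1.0, seed=9)
        amap = AnnotationMap.from_frame(ann)
        labels = pd.Series({g: max(a, 1) for g, a in arch.items()})
        cells = ClusterEnrichment(labels, amap, universe=genes).fit().cells
        from scipy import stats

        p = np.array([c.p for c in cells])
        d, ks_p = stats.kstest(p, "uniform")
        # discreteness pushes mass upward; uniformity holds approximately
        assert ks_p > 0.01 or p.mean() > 0.5

    def test_planted_term_detected(self):
        genes, arch = self._arch(5000, seed=2)
        # archetype 5 members as the "cluster"
        members = [g for g, a in arch.items() if a == 5]
        ann, manifest = simulate_annotations(
            genes, arch, n_terms=100, terms_per_gene=5.0,
            enriched_terms_per_archetype=1, fold_enrichment=8.0, seed=10,
        )
        term = manifest["enriched_terms"]["5"][0]
        amap = AnnotationMap.from_frame(ann)
        labels = pd.Series({g: (1 if a == 5 else 2) for g, a in arch.items()})
        cells = ClusterEnrichment(labels, amap, universe=genes).fit().cells
        cell = next(c for c in cells if c.cluster_id == 1 and c.category_id == term)
        assert cell.p < 1e-4

    def test_zero_terms_per_gene_degenerate(self):
        genes, arch = self._arch(100)
        ann, _ = simulate_annotations(genes, arch, n_terms=50, terms_per_gene=0.0, seed=1)
        assert len(ann) == 0
        assert len(AnnotationMap.from_frame(ann)) == 0

    def test_too_many_enriched_terms_rejected(self):
        genes, arch = self._arch(100)
        with pytest.raises(ValueError):
            simulate_annotations(genes, arch, n_terms=5, enriched_terms_per_archetype=2)


def test_trajectory_generator_reproducible():
    a, la = simulate_trajectories(100, 0.3, seed=1)
    b, lb = simulate_trajectories(100, 0.3, seed=1)
    assert np.array_equal(a.z, b.z)
    assert (la == lb).all()
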