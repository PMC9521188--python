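"""Synthetic flg22-style time-course data with known planted structure.

Everything downstream of read mapping is exercised on data generated
here: negative-binomial count matrices over the time points
{0, 0.5, 1, 3, 6, 12} h with 10 planted trajectory archetypes (4 down-
and 6 up-regulated, extrema at distinct time points), random genomes
with strand-aware gene models whose promoters carry archetype-dependent
planted cis-elements, and annotation maps with archetype-enriched terms.
A :class:`TruthManifest` records every planted value so recovery can be
scored without re-simulation.

NB parameterization: variance = mu + phi * mu^2 (dispersion phi).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_TIMEPOINTS = (0.0, 0.5, 1.0, 3.0, 6.0, 12.0)

#: log2 offsets from baseline per archetype (rows 1..10) at the default
#: time points. Archetypes 1-4 are down-regulated (troughs at 12, 3, 6
#: and 1 h; archetype 2 recovers by 12 h), 5-10 up-regulated (peaks at
#: 0.5, 1, 3, 6, 6+12, 12 h).
DEFAULT_ARCHETYPE_DELTAS = np.array(
    [
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],        # 0: null
        [0.0, -0.3, -0.7, -1.2, -1.8, -2.5],   # 1: steady decline
        [0.0, -0.7, -1.5, -2.4, -1.2, 0.0],    # 2: trough 3 h, recovered
        [0.0, -0.3, -0.8, -1.8, -2.4, -1.4],   # 3: trough 6 h, partial recovery
        [0.0, -1.3, -2.3, -1.6, -1.0, -0.5],   # 4: early repression
        [0.0, 2.5, 1.8, 0.8, 0.3, 0.1],        # 5: peak 0.5 h
        [0.0, 1.2, 2.5, 1.5, 0.6, 0.2],        # 6: peak 1 h
        [0.0, 0.3, 1.2, 2.5, 1.4, 0.5],        # 7: peak 3 h
        [0.0, 0.1, 0.5, 1.5, 2.5, 1.2],        # 8: peak 6 h
        [0.0, 0.05, 0.3, 1.0, 2.0, 2.2],       # 9: high at 6 and 12 h
        [0.0, 0.0, 0.1, 0.4, 1.2, 2.5],        # 10: late induction
    ]
)

#: Default motif-planting odds per archetype: W-boxes ahead of the early
#: up-regulated waves (WRKY-driven), G-box/ABRE in the flg22-induced
#: clusters, CG-1 ahead of down-regulated genes.
DEFAULT_MOTIF_ODDS = {
    5: {"W-box": 4.0, "G-box": 2.0},
    6: {"W-box": 4.0, "G-box": 2.0},
    7: {"W-box": 2.0},
    1: {"CG-1": 3.0},
    3: {"CG-1": 3.0},
    4: {"CG-1": 3.0},
}


def stage_seed(seed: int, stage: str) -> int:
    """Derive an independent per-stage seed from a run seed."""
    return (int(seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class TimeCourseDesign:
    """Sampling design of the time course."""

    timepoints_h: tuple = DEFAULT_TIMEPOINTS
    replicates_per_timepoint: int = 3
    n_genes: int = 2000
    library_size_target: float = 2e6

    def __post_init__(self):
        tp = tuple(float(t) for t in self.timepoints_h)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if tp[0] != 0.0:
            raise ValueError("first timepoint must be the 0 h baseline")
        if self.replicates_per_timepoint < 2:
            raise ValueError("need at least 2 replicates per timepoint")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        self.timepoints_h = tp

    @property
    def n_samples(self) -> int:
        return len(self.timepoints_h) * self.replicates_per_timepoint

    def sample_sheet(self) -> pd.DataFrame:
        rows = [
            (f"T{t:g}h_r{r}", t, r)
            for t in self.timepoints_h
            for r in range(1, self.replicates_per_timepoint + 1)
        ]
        df = pd.DataFrame(rows, columns=["sample_id", "timepoint_h", "replicate"])
        return df.set_index("sample_id")


@dataclass
class PlantedTruth:
    """Ground-truth generative parameters.

    mu/phi are per-gene NB baseline means and dispersions; ``archetype``
    maps each gene to 0 (null) or a trajectory archetype 1..10 whose
    log2 offsets from baseline are the rows of ``deltas`` (row 0 = null).
    ``motif_odds`` gives per-archetype planting odds o for each motif
    (planting probability o/(1+o); numpy.inf forces planting).
    """

    mu: np.ndarray
    phi: np.ndarray
    archetype: np.ndarray
    deltas: np.ndarray = field(default_factory=lambda: DEFAULT_ARCHETYPE_DELTAS.copy())
    motif_odds: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MOTIF_ODDS.items()})
    seed: int = 0

    def __post_init__(self):
        self.mu = np.asarray(self.mu, float)
        self.phi = np.asarray(self.phi, float)
        self.archetype = np.asarray(self.archetype, int)
        self.deltas = np.asarray(self.deltas, float)
        for name, arr in (("mu", self.mu), ("phi", self.phi)):
            bad = np.nonzero(~(arr > 0))[0]
            if bad.size:
                raise ValueError(f"non-positive {name} for gene index {bad[0]}")
        if self.archetype.min() < 0 or self.archetype.max() >= self.deltas.shape[0]:
            raise ValueError("archetype ids must index rows of deltas")
        if np.any(self.deltas[:, 0] != 0):
            raise ValueError("archetype offsets must be anchored at 0 for the baseline")
        n_arch = self.deltas.shape[0] - 1
        for a in range(1, n_arch + 1):
            d = self.deltas[a]
            down = a <= (n_arch - 6 if n_arch >= 6 else n_arch // 2)
            if down and not (d.min() < 0 and d.max() <= 0):
                raise ValueError(f"archetype {a} must be down-regulated (min<0, max<=0)")
            if not down and not (d.max() > 0 and d.min() >= 0):
                raise ValueError(f"archetype {a} must be up-regulated (max>0, min>=0)")

    @property
    def n_genes(self) -> int:
        return self.mu.size


def default_truth(
    design: TimeCourseDesign,
    seed: int = 0,
    frac_null: float = 0.0,
    archetype_weights=None,
) -> PlantedTruth:
    """Realistic default truth: log-normal baseline means, a dispersion
    trend phi ~ 0.04 + 2/mu with log-normal scatter, archetypes assigned
    uniformly (or by ``archetype_weights``) to the non-null genes."""
    rng = np.random.default_rng(stage_seed(seed, "truth"))
    n = design.n_genes
    mu = rng.lognormal(mean=np.log(80.0), sigma=1.0, size=n)
    phi = (0.04 + 2.0 / mu) * rng.lognormal(0.0, 0.25, size=n)
    deltas = archetype_deltas_for(design.timepoints_h)
    n_arch = deltas.shape[0] - 1
    arch = np.zeros(n, dtype=int)
    signal = rng.random(n) >= frac_null
    if archetype_weights is None:
        archetype_weights = np.ones(n_arch)
    w = np.asarray(archetype_weights, float)
    arch[signal] = rng.choice(np.arange(1, n_arch + 1), size=signal.sum(), p=w / w.sum())
    return PlantedTruth(mu=mu, phi=phi, archetype=arch, deltas=deltas, seed=seed)


def archetype_deltas_for(timepoints_h) -> np.ndarray:
    """Archetype offsets on an arbitrary time grid (linear interpolation
    of the default profiles, re-anchored to 0 at baseline)."""
    tp = np.asarray(timepoints_h, float)
    if tuple(tp) == DEFAULT_TIMEPOINTS:
        return DEFAULT_ARCHETYPE_DELTAS.copy()
    base = np.asarray(DEFAULT_TIMEPOINTS)
    out = np.vstack([np.interp(tp, base, row) for row in DEFAULT_ARCHETYPE_DELTAS])
    out[:, 0] = 0.0
    return out


class TruthManifest(dict):
    """JSON-serializable record of everything planted."""

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self, fh, indent=1, sort_keys=True, default=_jsonify)

    @classmethod
    def read(cls, path) -> "TruthManifest":
        with open(path) as fh:
            return cls(json.load(fh))


def _jsonify(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def gene_ids(n: int) -> list:
    return [f"gene{i + 1:05d}" for i in range(n)]


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def simulate_counts(design: TimeCourseDesign, truth: PlantedTruth):
    """Draw an NB count matrix under the planted trajectories.

    Counts for gene g in a replicate of time point t have mean
    ``mu_g * 2**delta[a(g), t] * s_j`` with per-sample library-size
    factors s_j ~ log-uniform[0.7, 1.4], and NB variance m + phi m^2
    at mean m. Returns ``(CountMatrix, TruthManifest)``.
    """
    from .deg import CountMatrix

    if truth.n_genes != design.n_genes:
        raise ValueError(
            f"design has {design.n_genes} genes but truth has {truth.n_genes}"
        )
    if truth.deltas.shape[1] != len(design.timepoints_h):
        raise ValueError("truth.deltas columns must match design timepoints")
    rng = np.random.default_rng(stage_seed(truth.seed, "counts"))
    sheet = design.sample_sheet()
    n_samp = len(sheet)
    s = np.exp(rng.uniform(np.log(0.7), np.log(1.4), size=n_samp))
    tp_index = {t: i for i, t in enumerate(design.timepoints_h)}
    mean = np.empty((design.n_genes, n_samp))
    for j, (sid, row) in enumerate(sheet.iterrows()):
        ti = tp_index[float(row["timepoint_h"])]
        mean[:, j] = truth.mu * 2.0 ** truth.deltas[truth.archetype, ti] * s[j]
    # NB draw: shape r = 1/phi, p = r/(r+m); phi -> 0 is effectively Poisson
    r = 1.0 / np.maximum(truth.phi, 1e-12)[:, None]
    counts = rng.negative_binomial(r, r / (r + mean))
    ids = gene_ids(design.n_genes)
    cm = CountMatrix(pd.DataFrame(counts, index=ids, columns=sheet.index), sheet)
    manifest = TruthManifest(
        seed=truth.seed,
        gene_archetype=dict(zip(ids, truth.archetype)),
        mu=dict(zip(ids, truth.mu)),
        phi=dict(zip(ids, truth.phi)),
        deltas=truth.deltas,
        timepoints_h=list(design.timepoints_h),
        library_factors=dict(zip(sheet.index, s)),
    )
    return cm, manifest


def write_bundle(
    out_dir,
    n_genes: int = 2000,
    seed: int = 0,
    frac_null: float = 0.0,
    contig_length: int = 300000,
    design_kwargs: dict | None = None,
):
    """Write a complete synthetic input bundle for the pipeline.

    Produces counts.tsv + samples.tsv, genome.fasta + genes.gff3,
    annotations.tsv (GO-style) and tf_families.tsv, plus truth manifests.
    Returns the output directory as a Path.
    """
    from pathlib import Path

    from .io import write_counts, write_fasta, write_table
    from .motifs import load_motifs

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = TimeCourseDesign(n_genes=n_genes, **(design_kwargs or {}))
    truth = default_truth(design, seed=seed, frac_null=frac_null)
    cm, cmanifest = simulate_counts(design, truth)
    write_counts(cm, out / "counts.tsv", out / "samples.tsv")
    cmanifest.write(out / "truth_counts.json")
    motifs = load_motifs()
    genome, gff, gmanifest = simulate_genome(n_genes, contig_length, 1000, motifs, truth)
    write_fasta(genome, out / "genome.fasta")
    (out / "genes.gff3").write_text(gff)
    gmanifest.write(out / "truth_genome.json")
    arch = {g: int(a) for g, a in cmanifest["gene_archetype"].items()}
    ann, amanifest = simulate_annotations(list(cm.gene_ids), arch, seed=seed)
    write_table(ann, out / "annotations.tsv")
    amanifest.write(out / "truth_annotations.json")
    tf, tmanifest = simulate_annotations(
        list(cm.gene_ids), arch, n_terms=30, terms_per_gene=0.6,
        enriched_terms_per_archetype=1, fold_enrichment=6.0,
        seed=seed + 1, category_class="TF-family",
    )
    write_table(tf.rename(columns={"term_id": "family"}), out / "tf_families.tsv")
    tmanifest.write(out / "truth_tf.json")
    return out


def simulate_trajectories(
    n_genes: int = 2000,
    noise_sd: float = 0.3,
    seed: int = 0,
    timepoints_h=DEFAULT_TIMEPOINTS,
    deltas: np.ndarray | None = None,
):
    """Noisy z-profiles drawn directly from the trajectory archetypes.

    Each gene takes one of the 10 archetypes (uniformly), whose z-scored
    log2-offset profile is perturbed with i.i.d. Gaussian noise of sd
    ``noise_sd`` (in z units) and re-standardized. Returns
    ``(TrajectoryMatrix, labels)`` with the planted archetype per gene —
    the benchmark input for cluster-recovery scoring.
    """
    from .cluster import TrajectoryMatrix, zscale
    import pandas as pd

    if deltas is None:
        deltas = archetype_deltas_for(timepoints_h)
    arche = deltas[1:]  # drop the null row
    zarch = (arche - arche.mean(axis=1, keepdims=True)) / arche.std(axis=1, ddof=1, keepdims=True)
    rng = np.random.default_rng(stage_seed(seed, "trajectories"))
    labels = rng.integers(1, zarch.shape[0] + 1, size=n_genes)
    raw = zarch[labels - 1] + rng.normal(0.0, noise_sd, size=(n_genes, zarch.shape[1]))
    df = pd.DataFrame(raw, index=gene_ids(n_genes), columns=list(timepoints_h))
    traj = zscale(df)
    keep = pd.Series(labels, index=df.index).loc[traj.gene_ids]
    return traj, keep


# ---------------------------------------------------------------------------
# genome + gene models
# ---------------------------------------------------------------------------

_GENE_BODY = 300  # simulated CDS length (bp)
_SPACER = 50


def simulate_genome(
    n_genes: int,
    contig_length: int,
    promoter_length: int,
    motif_dict,
    truth: PlantedTruth,
    gene_body: int = _GENE_BODY,
):
    """Random ACGT contigs with one single-CDS gene model per gene and
    archetype-dependent cis-elements planted in promoters.

    Each gene occupies a non-overlapping slot (promoter window + gene
    body + spacer) on a contig, with a random strand. For each motif m
    with odds ``o = truth.motif_odds[archetype][m]``, the promoter
    receives a planted instance with probability ``o/(1+o)`` (``inf``
    forces one); the instance (a uniformly drawn matching word) is
    written at a random promoter-local position, on the promoter's sense
    strand, so strand-aware extraction recovers it verbatim.

    Returns ``(contigs: dict, gff3: str, TruthManifest)`` where the
    manifest lists every planted occurrence (gene, motif, promoter-local
    1-based position, site).
    """
    rng = np.random.default_rng(stage_seed(truth.seed, "genome"))
    slot = promoter_length + gene_body + _SPACER
    per_contig = contig_length // slot
    if per_contig < 1:
        raise ValueError(
            f"contig_length={contig_length} too short for one gene "
            f"(needs {slot} = promoter {promoter_length} + body {gene_body} + spacer {_SPACER})"
        )
    motifs = {m.name: m for m in motif_dict}
    ids = gene_ids(n_genes)
    bases = np.array(list("ACGT"))
    contigs: dict = {}
    gff_lines = ["##gff-version 3"]
    planted: list = []
    for i, gid in enumerate(ids):
        ci, slot_i = divmod(i, per_contig)
        contig = f"chr{ci + 1:02d}"
        if contig not in contigs:
            contigs[contig] = list(rng.choice(bases, size=contig_length))
        x = slot_i * slot  # 0-based slot origin
        strand = "+" if rng.random() < 0.5 else "-"
        # build the sense promoter, plant motifs into it
        promoter = list(rng.choice(bases, size=promoter_length))
        arch = int(truth.archetype[i]) if i < truth.n_genes else 0
        for mname, odds in sorted(truth.motif_odds.get(arch, {}).items()):
            if mname not in motifs:
                raise KeyError(f"motif {mname!r} not in the supplied dictionary")
            if odds < 0:
                raise ValueError(f"negative planting odds for motif {mname!r}")
            prob = 1.0 if np.isinf(odds) else odds / (1.0 + odds)
            if rng.random() < prob:
                pat = motifs[mname]
                kmers = pat.matching_kmers()
                site = kmers[rng.integers(len(kmers))]
                # avoid clobbering an earlier planted site in this promoter
                occupied = [
                    (r["position"] - 1, r["position"] - 1 + len(r["site"]))
                    for r in planted
                    if r["gene_id"] == gid
                ]
                pos = None
                for _ in range(100):
                    cand = int(rng.integers(0, promoter_length - len(site) + 1))
                    if all(cand + len(site) <= a or cand >= b for a, b in occupied):
                        pos = cand
                        break
                if pos is None:
                    raise RuntimeError(
                        f"could not place motif {mname!r} in the promoter of {gid}"
                    )
                promoter[pos : pos + len(site)] = list(site)
                planted.append(
                    {"gene_id": gid, "motif": mname, "position": pos + 1, "site": site}
                )
        seq = contigs[contig]
        if strand == "+":
            # promoter [x, x+L), CDS [x+L, x+L+body) (0-based)
            seq[x : x + promoter_length] = promoter
            cds_start, cds_end = x + promoter_length + 1, x + promoter_length + gene_body
        else:
            # CDS [x, x+body), promoter genomic window holds revcomp(sense)
            from .motifs import revcomp

            rc = list(revcomp("".join(promoter)))
            seq[x + gene_body : x + gene_body + promoter_length] = rc
            cds_start, cds_end = x + 1, x + gene_body
        for ftype, attrs in (
            ("gene", f"ID={gid}"),
            ("mRNA", f"ID={gid}.1;Parent={gid}"),
            ("CDS", f"ID={gid}.1.cds;Parent={gid}.1"),
        ):
            phase = "0" if ftype == "CDS" else "."
            gff_lines.append(
                f"{contig}\tptiseq\t{ftype}\t{cds_start}\t{cds_end}\t.\t{strand}\t{phase}\t{attrs}"
            )
        planted_strand = strand
        # manifest strand recorded for bookkeeping
        if planted and planted[-1]["gene_id"] == gid:
            for rec in planted:
                if rec["gene_id"] == gid:
                    rec["strand"] = planted_strand
    genome = {c: "".join(s) for c, s in contigs.items()}
    manifest = TruthManifest(
        seed=truth.seed,
        promoter_length=promoter_length,
        gene_body=gene_body,
        planted_motifs=planted,
        gene_strands={},
    )
    return genome, "\n".join(gff_lines) + "\n", manifest


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def simulate_annotations(
    genes,
    archetype_of,
    n_terms: int = 200,
    terms_per_gene: float = 4.0,
    enriched_terms_per_archetype: int = 2,
    fold_enrichment: float = 8.0,
    seed: int = 0,
    category_class: str = "GO",
):
    """Gene -> term map with archetype-enriched designated terms.

    Background: every (gene, term) pair is annotated independently with
    probability ``terms_per_gene / n_terms``. Each archetype gets
    ``enriched_terms_per_archetype`` designated terms whose members are
    annotated at ``fold_enrichment`` times the background rate (capped
    at 1). Returns ``(DataFrame[gene_id, term_id], TruthManifest)``.
    """
    if fold_enrichment < 1:
        raise ValueError("fold_enrichment must be >= 1")
    genes = list(genes)
    arch = np.asarray([archetype_of[g] for g in genes], int)
    archetypes = sorted(set(arch[arch > 0]))
    need = enriched_terms_per_archetype * len(archetypes)
    if need > n_terms:
        raise ValueError(
            f"{need} enriched terms requested but only {n_terms} terms available"
        )
    rng = np.random.default_rng(stage_seed(seed, "annotations"))
    q = terms_per_gene / n_terms if n_terms else 0.0
    terms = [f"T{i + 1:04d}" for i in range(n_terms)]
    enriched = {}
    for j, a in enumerate(archetypes):
        enriched[a] = terms[
            j * enriched_terms_per_archetype : (j + 1) * enriched_terms_per_archetype
        ]
    prob = np.full((len(genes), n_terms), q)
    term_idx = {t: i for i, t in enumerate(terms)}
    for a, tlist in enriched.items():
        rows = np.nonzero(arch == a)[0]
        for t in tlist:
            prob[rows, term_idx[t]] = min(1.0, fold_enrichment * q)
    hit = rng.random(prob.shape) < prob
    gi, ti = np.nonzero(hit)
    df = pd.DataFrame({"gene_id": [genes[i] for i in gi], "term_id": [terms[j] for j in ti]})
    manifest = TruthManifest(
        seed=seed,
        n_terms=n_terms,
        background_rate=q,
        fold_enrichment=fold_enrichment,
        enriched_terms={str(a): t for a, t in enriched.items()},
        category_class=category_class,
    )
    return df, manifest
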