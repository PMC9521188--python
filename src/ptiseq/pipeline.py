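"""End-to-end orchestration: DEG calling -> trajectory clustering ->
per-cluster over-representation of GO terms, TF families and promoter
cis-elements."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .cluster import (
    TrajectoryKMeans,
    gap_statistic,
    replicate_mean_profiles,
    zscale,
)
from .deg import DifferentialExpression
from .enrich import AnnotationMap, ClusterEnrichment
from .io import RunConfig, RunManifest, read_counts, sha256, write_table
from .motifs import load_motifs, presence_table
from .promoters import extract_promoters
from .simulate import stage_seed

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full analysis and write every stage output.

    Stages: deg -> cluster -> [gap] -> enrich (GO / TF-family / motif,
    whichever inputs are configured). Outputs land in ``config.out_dir``;
    the manifest is written there last (atomically). A stage failure
    aborts with a partial manifest on disk and re-raises as StageError.
    """
    want_motifs = config.genome is not None or config.gff is not None
    config.validate_paths(require_promoters=want_motifs)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=vars(config).copy(), version=__version__)
    manifest.stamp_start()
    for key in ("counts", "sample_sheet", "genome", "gff", "annotations", "tf_families", "motifs"):
        p = getattr(config, key)
        if p is not None:
            manifest.input_checksums[key] = sha256(p)
    try:
        _run_stages(config, out, manifest)
    except Exception as e:  # partial manifest, then propagate
        manifest.stamp_finish(status=f"failed: {e}")
        manifest.write(out / "run_manifest.json")
        if isinstance(e, StageError):
            raise
        raise StageError("setup", e) from e
    manifest.stamp_finish()
    manifest.write(out / "run_manifest.json")
    return manifest


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                log.info("stage %s", name)
                return fn(*a, **kw)
            except StageError:
                raise
            except Exception as e:
                raise StageError(name, e) from e

        return wrapped

    return deco


@_stage("deg")
def _deg_stage(config, out, manifest):
    cm = read_counts(config.counts, config.sample_sheet)
    model = DifferentialExpression(cm)
    res = model.fit()
    degs = res.filter_degs(config.fc, config.fdr, config.pval)
    write_table(res.contrasts, out / "contrasts.tsv")
    write_table(degs.to_frame(), out / "deg_lists.tsv")
    counts_tbl = degs.counts()
    counts_tbl.to_csv(out / "deg_counts.tsv", sep="\t", na_rep="NA")
    manifest.stage_rows["contrasts"] = len(res.contrasts)
    manifest.stage_rows["degs_union"] = len(degs.union)
    log.info(
        "DEG filter: |log2FC| > %g applied with FDR < %g and p < %g",
        __import__("numpy").log2(config.fc), config.fdr, config.pval,
    )
    return cm, model, res, degs


@_stage("cluster")
def _cluster_stage(config, out, manifest, cm, model, degs):
    profiles = replicate_mean_profiles(cm, model.factors).loc[degs.union]
    traj = zscale(profiles)
    seed = stage_seed(config.seed, "kmeans")
    results = TrajectoryKMeans(traj, k=config.k, seed=seed, n_restarts=config.restarts).fit()
    assign = pd.DataFrame(
        {
            "gene_id": results.labels.index,
            "cluster": results.labels.to_numpy(),
        }
    ).merge(results.summary()[["direction"]], left_on="cluster", right_index=True)
    write_table(assign, out / "cluster_assignment.tsv")
    results.centroids.to_csv(out / "centroids.tsv", sep="\t", na_rep="NA")
    zdf = traj.to_frame().loc[results.labels.sort_values(kind="stable").index]
    zdf.insert(0, "cluster", results.labels.loc[zdf.index])
    zdf.to_csv(out / "z_matrix.tsv", sep="\t", index_label="gene_id", na_rep="NA")
    manifest.stage_rows["clustered_genes"] = int(results.labels.size)
    manifest.seeds["kmeans"] = seed
    return traj, results


@_stage("gap")
def _gap_stage(config, out, manifest, traj):
    seed = stage_seed(config.seed, "gap")
    curve = gap_statistic(
        traj,
        k_range=range(config.gap_k_min, config.gap_k_max + 1),
        B=config.gap_b,
        seed=seed,
    )
    curve.to_frame().to_csv(out / "gap_curve.tsv", sep="\t", na_rep="NA")
    manifest.metrics["gap_selected_k"] = int(curve.selected_k)
    manifest.seeds["gap"] = seed


@_stage("enrich")
def _enrich_stage(config, out, manifest, results, annmaps):
    all_cells = []
    for label, amap in annmaps:
        universe = (
            set(results.labels.index) if config.universe == "degs" else None
        )
        res = ClusterEnrichment(results, amap, universe=universe).fit()
        df = res.to_frame()
        write_table(df, out / f"enrichment_{label}.tsv")
        res.heatmap_matrix().to_csv(out / f"heatmap_{label}.tsv", sep="\t", na_rep="NA")
        manifest.stage_rows[f"enrichment_{label}"] = len(df)
        all_cells.append(df)
    return all_cells


def _run_stages(config: RunConfig, out: Path, manifest: RunManifest) -> None:
    cm, model, res, degs = _deg_stage(config, out, manifest)
    if not degs.union:
        raise StageError("cluster", ValueError("no DEGs passed the filter"))
    traj, results = _cluster_stage(config, out, manifest, cm, model, degs)
    if config.gap_b:
        _gap_stage(config, out, manifest, traj)

    annmaps = []
    if config.annotations:
        annmaps.append(("go", AnnotationMap.read_tsv(config.annotations, "GO")))
    if config.tf_families:
        annmaps.append(("tf", AnnotationMap.read_tsv(config.tf_families, "TF-family")))
    if config.genome and config.gff:
        proms = extract_promoters(config.genome, config.gff, config.promoter_length)
        proms.to_fasta(out / "promoters.fasta")
        proms.to_bed(out / "promoters.bed")
        motifs = load_motifs(config.motifs)
        table, positions = presence_table(
            proms, motifs, strand_mode=config.strand_mode, with_positions=True
        )
        table.to_csv(out / "motif_presence.tsv", sep="\t", na_rep="NA")
        write_table(positions, out / "motif_positions.tsv")
        manifest.stage_rows["promoters"] = len(proms)
        annmaps.append(("motif", AnnotationMap.from_presence(table, "motif")))
    if annmaps:
        _enrich_stage(config, out, manifest, results, annmaps)
    manifest.metrics["universe_mode"] = config.universe
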