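"""Readers, writers and run configuration.

All tables are TSV with header rows; missing values are written as "NA".
Genomic coordinates are GFF3-style 1-based inclusive everywhere except
BED output (0-based half-open, converted at the boundary only).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .deg import CountMatrix, adjust_bh

log = logging.getLogger(__name__)

NA = "NA"


def read_counts(path, sample_sheet_path) -> CountMatrix:
    """Read a genes × samples counts TSV plus its sample sheet.

    The counts file has gene_id in the first column; the sample sheet
    (sample_id, timepoint_h, replicate) must cover every count column.
    Negative/non-numeric counts and duplicate IDs are rejected;
    non-integer counts are rounded with a warning (RSEM-style expected
    counts tolerated).
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    bad = counts.columns[[not pd.api.types.is_numeric_dtype(counts[c]) for c in counts.columns]]
    if len(bad):
        col = bad[0]
        row = counts.index[pd.to_numeric(counts[col], errors="coerce").isna()][0]
        raise ValueError(f"non-numeric count at gene {row!r}, sample {col!r}")
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    if "sample_id" not in sheet.columns:
        raise ValueError("sample sheet must have a 'sample_id' column")
    sheet = sheet.set_index("sample_id")
    return CountMatrix(counts, sheet)


def write_counts(cm: CountMatrix, counts_path, sheet_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id", na_rep=NA)
    cm.samples.to_csv(sheet_path, sep="\t", index_label="sample_id", na_rep=NA)


def read_stats_table(path) -> pd.DataFrame:
    """Read a precomputed per-contrast statistics table.

    Expected columns: gene_id, timepoint_h, log2FC, p and optionally FDR
    (the dialect of published per-contrast statistics tables). If FDR is
    absent, BH adjustment is
    applied within each time point. p-values outside [0, 1] are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "timepoint_h", "log2FC", "p"):
        if col not in df.columns:
            raise ValueError(f"statistics table missing mandatory column {col!r}")
    pv = df["p"].dropna()
    if ((pv < 0) | (pv > 1)).any():
        bad = pv[(pv < 0) | (pv > 1)].iloc[0]
        raise ValueError(f"p-value out of [0, 1]: {bad}")
    if "FDR" not in df.columns:
        df = df.copy()
        df["FDR"] = np.nan
        for t, grp in df.groupby("timepoint_h"):
            ok = grp["p"].notna()
            df.loc[grp.index[ok], "FDR"] = adjust_bh(grp.loc[ok, "p"].to_numpy())
    return df


def write_table(df: pd.DataFrame, path, index=False, index_label=None) -> None:
    df.to_csv(path, sep="\t", index=index, index_label=index_label, na_rep=NA)


def write_fasta(contigs: dict, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    counts: str | None = None
    sample_sheet: str | None = None
    genome: str | None = None
    gff: str | None = None
    motifs: str | None = None          # None -> packaged dictionary
    annotations: str | None = None     # gene_id<TAB>term TSV (GO-style)
    tf_families: str | None = None     # gene_id<TAB>family TSV
    out_dir: str = "ptiseq_out"
    fc: float = 2.0
    fdr: float = 0.01
    pval: float = 0.01
    k: int = 10
    seed: int = 0
    restarts: int = 25
    gap_b: int = 0                     # 0 disables the gap-curve stage
    gap_k_min: int = 2
    gap_k_max: int = 13
    strand_mode: str = "both"
    universe: str = "annotation"       # 'annotation' or 'degs'
    promoter_length: int = 1000

    def __post_init__(self):
        if not (self.fc >= 1 and 0 < self.fdr <= 1 and 0 < self.pval <= 1):
            raise ValueError("thresholds out of range (fc >= 1, fdr/pval in (0, 1])")
        if self.strand_mode not in ("both", "given"):
            raise ValueError("strand_mode must be 'both' or 'given'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate_paths(self, require_promoters: bool) -> None:
        needed = {"counts": self.counts, "sample_sheet": self.sample_sheet}
        if require_promoters:
            needed.update({"genome": self.genome, "gff": self.gff})
        missing = [k for k, v in needed.items() if v is None]
        if missing:
            raise FileNotFoundError(f"config missing required inputs: {missing}")
        absent = [k for k, v in needed.items() if v is not None and not Path(v).exists()]
        if absent:
            raise FileNotFoundError(f"input files not found: {absent}")


@dataclass
class RunManifest:
    """Record of a pipeline run sufficient to re-execute it."""

    config: dict
    version: str = ""
    input_checksums: dict = field(default_factory=dict)
    stage_rows: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""
    status: str = "incomplete"

    def stamp_start(self):
        self.started = datetime.now(timezone.utc).isoformat()

    def stamp_finish(self, status="complete"):
        self.finished = datetime.now(timezone.utc).isoformat()
        self.status = status

    def write(self, path) -> None:
        tmp = Path(str(path) + ".tmp")
        with open(tmp, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
        tmp.replace(path)  # atomic on POSIX
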