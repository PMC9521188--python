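"""Strand-aware extraction of 1-kb promoter windows upstream of start codons.

Coordinates are GFF3 1-based inclusive throughout; conversion to BED's
0-based half-open convention happens only when writing BED.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import gffutils
from Bio import SeqIO

log = logging.getLogger(__name__)

DEFAULT_PROMOTER_LENGTH = 1000


@dataclass(frozen=True)
class Promoter:
    """One promoter window.

    ``sequence`` is the sense-strand context immediately 5' of the
    translation start (reverse-complemented for minus-strand genes);
    ``start``/``end`` are 1-based inclusive genomic coordinates.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    sequence: str
    truncated: bool

    def __len__(self) -> int:
        return len(self.sequence)


class PromoterSet(dict):
    """gene_id -> :class:`Promoter` mapping with FASTA/BED writers."""

    def sequences(self) -> dict:
        return {g: p.sequence for g, p in self.items()}

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for p in self.values():
                trunc = "|truncated" if p.truncated else ""
                fh.write(f">{p.gene_id}|{p.contig}:{p.start}-{p.end}({p.strand}){trunc}\n")
                for i in range(0, len(p.sequence), 60):
                    fh.write(p.sequence[i : i + 60] + "\n")

    def to_bed(self, path) -> None:
        # BED6: 0-based half-open
        with open(path, "w") as fh:
            for p in self.values():
                fh.write(
                    f"{p.contig}\t{p.start - 1}\t{p.end}\t{p.gene_id}\t0\t{p.strand}\n"
                )


def _revcomp(seq: str) -> str:
    from .motifs import revcomp

    return revcomp(seq)


def _cds_start(db: gffutils.FeatureDB, gene) -> tuple | None:
    """(contig, 5'-most CDS coordinate pair, strand) for a gene.

    With multiple mRNAs the transcript with the longest total CDS is used;
    the translation start is the 5'-most CDS coordinate on the gene's
    strand (leftmost `start` on +, rightmost `end` on -).
    """
    best = None  # (cds_len, cds_features)
    mrnas = list(db.children(gene, featuretype=("mRNA", "transcript")))
    parents = mrnas if mrnas else [gene]
    for parent in parents:
        cds = list(db.children(parent, featuretype="CDS"))
        if not cds:
            continue
        total = sum(f.end - f.start + 1 for f in cds)
        key = (total, min(f.start for f in cds))
        if best is None or key > best[0]:
            best = (key, cds)
    if best is None:
        return None
    cds = best[1]
    if gene.strand == "-":
        pos = max(f.end for f in cds)
    else:
        pos = min(f.start for f in cds)
    return gene.seqid, pos, gene.strand


def extract_promoters(
    genome,
    gff,
    promoter_length: int = DEFAULT_PROMOTER_LENGTH,
) -> PromoterSet:
    """Extract upstream promoter windows for every gene with a CDS.

    Parameters
    ----------
    genome : path to FASTA or mapping contig -> sequence string
    gff : path to a GFF3 file or a :class:`gffutils.FeatureDB`
    promoter_length : int
        Window length L. Plus strand: positions ``[start-L, start-1]``;
        minus strand: ``[end+1, end+L]`` reverse-complemented. Windows
        clipped at contig edges get ``truncated=True``.

    Genes without any CDS are skipped with a warning; a gene on a contig
    absent from the genome raises ``KeyError``.
    """
    if isinstance(genome, (str, bytes)) or hasattr(genome, "__fspath__"):
        contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome), "fasta")}
    else:
        contigs = {k: v.upper() for k, v in dict(genome).items()}
    if isinstance(gff, gffutils.FeatureDB):
        db = gff
    else:
        db = gffutils.create_db(
            str(gff), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    out = PromoterSet()
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        loc = _cds_start(db, gene)
        if loc is None:
            warnings.warn(f"gene {gene.id} has no CDS; skipped")
            continue
        contig, pos, strand = loc
        if contig not in contigs:
            raise KeyError(f"contig {contig!r} for gene {gene.id} missing from genome")
        clen = len(contigs[contig])
        if strand == "-":
            start, end = pos + 1, pos + promoter_length
            truncated = end > clen
            end = min(end, clen)
            if start > end:
                warnings.warn(f"gene {gene.id}: empty promoter window at contig edge; skipped")
                continue
            seq = _revcomp(contigs[contig][start - 1 : end])
        else:
            start, end = pos - promoter_length, pos - 1
            truncated = start < 1
            start = max(start, 1)
            if start > end:
                warnings.warn(f"gene {gene.id}: empty promoter window at contig edge; skipped")
                continue
            seq = contigs[contig][start - 1 : end]
        out[gene.id] = Promoter(
            gene_id=gene.id,
            contig=contig,
            start=start,
            end=end,
            strand=strand,
            sequence=seq,
            truncated=truncated,
        )
    return out
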