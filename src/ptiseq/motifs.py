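"""Degenerate cis-regulatory element patterns and promoter scanning.

Cis-elements are written as positional consensus strings over A/C/G/T with
``N`` for any base and bracketed alternation groups such as ``(A/G)``.
A pattern is compiled into a list of allowed-base sets, one per position;
a window matches when every window base is in the corresponding set.
An ``N`` in the *scanned sequence* never matches a non-N pattern position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Valid bases at a pattern position.
_BASES = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class MotifParseError(ValueError):
    """Raised when a consensus string cannot be parsed."""


@dataclass(frozen=True)
class MotifPattern:
    """A compiled degenerate consensus motif.

    Attributes
    ----------
    name : str
        Motif name (e.g. ``W-box``).
    tf_family : str
        Transcription-factor family the element is associated with.
    consensus : str
        The original consensus string.
    positions : tuple of frozenset
        Allowed bases at each position.
    """

    name: str
    tf_family: str
    consensus: str
    positions: tuple = field(repr=False)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_matching_kmers(self) -> int:
        """Number of distinct exact words the pattern matches."""
        n = 1
        for s in self.positions:
            n *= len(s)
        return n

    def regex(self) -> re.Pattern:
        """Overlap-tolerant compiled regex (lookahead capture)."""
        body = "".join(
            b if len(s) == 1 else "[" + b + "]"
            for s in self.positions
            for b in ["".join(sorted(s))]
        )
        return re.compile(r"(?=(" + body + r"))")

    def matching_kmers(self) -> list[str]:
        """Enumerate every exact word matching the pattern."""
        words = [""]
        for s in self.positions:
            words = [w + b for w in words for b in sorted(s)]
        return words


def compile_motif(consensus: str, name: str = "", tf_family: str = "") -> MotifPattern:
    """Parse a consensus string into a :class:`MotifPattern`.

    Parameters
    ----------
    consensus : str
        Pattern over ``{A,C,G,T,N}`` plus alternation groups ``(X/Y/...)``.

    Raises
    ------
    MotifParseError
        On empty input, unbalanced brackets or illegal characters; the
        message names the offending position.
    """
    if not consensus:
        raise MotifParseError("empty consensus string")
    positions: list[frozenset] = []
    i = 0
    s = consensus.upper()
    while i < len(s):
        c = s[i]
        if c == "(":
            j = s.find(")", i)
            if j < 0:
                raise MotifParseError(f"unbalanced '(' at position {i + 1} in {consensus!r}")
            alts = s[i + 1 : j].split("/")
            bad = [a for a in alts if a not in _BASES]
            if bad or not alts:
                raise MotifParseError(
                    f"illegal alternation {s[i:j + 1]!r} at position {i + 1} in {consensus!r}"
                )
            positions.append(frozenset(alts))
            i = j + 1
        elif c == "N":
            positions.append(frozenset(_BASES))
            i += 1
        elif c in _BASES:
            positions.append(frozenset(c))
            i += 1
        else:
            raise MotifParseError(f"illegal character {c!r} at position {i + 1} in {consensus!r}")
    return MotifPattern(name=name, tf_family=tf_family, consensus=consensus, positions=tuple(positions))


@dataclass(frozen=True)
class MotifMatch:
    """One motif occurrence in a promoter, 1-based on the sense promoter."""

    position: int
    strand: str  # '+' = as given, '-' = hit on the reverse complement
    site: str


def scan_promoter(sequence: str, motif: MotifPattern, strand_mode: str = "both") -> list[MotifMatch]:
    """All occurrences of ``motif`` in ``sequence``.

    ``strand_mode='given'`` scans the sequence as provided; ``'both'``
    additionally scans its reverse complement, mapping hit positions back
    to coordinates on the given sequence (position of the hit's leftmost
    base on the given strand).
    """
    if strand_mode not in ("given", "both"):
        raise ValueError(f"strand_mode must be 'given' or 'both', got {strand_mode!r}")
    seq = sequence.upper()
    w = len(motif)
    if w == 0 or len(seq) < w:
        return []
    rx = motif.regex()
    hits = [MotifMatch(m.start() + 1, "+", m.group(1)) for m in rx.finditer(seq)]
    if strand_mode == "both":
        rc = revcomp(seq)
        L = len(seq)
        for m in rx.finditer(rc):
            # leftmost base of the hit on the given strand
            pos = L - (m.start() + w) + 1
            hits.append(MotifMatch(pos, "-", m.group(1)))
    return sorted(hits, key=lambda h: (h.position, h.strand))


def presence_table(
    promoters,
    motifs: Iterable[MotifPattern],
    strand_mode: str = "both",
    with_positions: bool = False,
):
    """Gene × motif boolean presence matrix.

    Parameters
    ----------
    promoters : PromoterSet or mapping gene_id -> sequence
    motifs : iterable of MotifPattern
    strand_mode : {'both', 'given'}
    with_positions : bool
        Also return a long-format DataFrame of individual matches
        (gene_id, motif, position, strand, site).

    Returns
    -------
    pandas.DataFrame of bool, genes × motifs — or ``(table, positions)``.
    """
    seqs = promoters.sequences() if hasattr(promoters, "sequences") else dict(promoters)
    motifs = list(motifs)
    table = pd.DataFrame(
        False, index=list(seqs), columns=[m.name for m in motifs], dtype=bool
    )
    rows = []
    for gene, seq in seqs.items():
        for m in motifs:
            hits = scan_promoter(seq, m, strand_mode)
            if hits:
                table.at[gene, m.name] = True
                if with_positions:
                    rows.extend(
                        (gene, m.name, h.position, h.strand, h.site) for h in hits
                    )
    table.index.name = "gene_id"
    if with_positions:
        pos = pd.DataFrame(rows, columns=["gene_id", "motif", "position", "strand", "site"])
        return table, pos
    return table


def load_motifs(path=None) -> list[MotifPattern]:
    """Load a motif dictionary TSV (columns: name, family, consensus).

    With no path, returns the packaged dictionary of 15 flg22-responsive
    promoter elements (GCC-box, DRE/CRT, DRE-like, Myc-related, G-box,
    G-box-like, ABRE-like, ACTCAT, TGA, AtMyb1-4, W-box, CG-1).
    """
    if path is None:
        with resources.files("ptiseq.data").joinpath("cis_elements.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    missing = {"name", "family", "consensus"} - set(df.columns)
    if missing:
        raise ValueError(f"motif dictionary missing columns: {sorted(missing)}")
    return [
        compile_motif(r.consensus, name=r.name, tf_family=r.family)
        for r in df.itertuples(index=False)
    ]
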