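"""Promoter extraction and IUPAC consensus motif scanning.

Supports the post-ciliogenesis chemoreceptor analysis: the region upstream
of each gene's start codon (default 1000 bp) is pulled from a genome FASTA
using BED6 gene intervals, reported 5'->3' on the gene's coding strand, and
scanned for an IUPAC consensus element (default ``CANNTG``, the canonical
bHLH E-box).  Scanning reports every (possibly overlapping) occurrence with
a 0-based offset on the promoter's forward coordinate system; in
both-strands mode the reverse complement is scanned too and palindromic
motifs yield two mirrored hits, which presence queries deduplicate.

An ``N`` in the *sequence* is treated as an unknown base: it matches only
the fully degenerate code ``N`` in the motif, never a specific code.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .enrichment import Contingency2x2, EnrichmentResult, chi_squared_2x2

__all__ = [
    "IUPAC_CODES",
    "IUPACMotif",
    "MotifHit",
    "PromoterSet",
    "BedFormatError",
    "read_promoter_fasta",
    "write_promoter_fasta",
    "extract_promoters",
    "scan_motif",
    "genes_with_motif",
    "motif_enrichment",
    "reverse_complement",
]

logger = logging.getLogger(__name__)

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_SEQ_RE = re.compile(r"^[ACGTN]*$")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide (or IUPAC) string."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


class BedFormatError(ValueError):
    """A BED line could not be parsed as BED6."""


@dataclass(frozen=True)
class IUPACMotif:
    """A consensus motif over the 15-letter IUPAC nucleotide alphabet."""

    pattern: str

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        object.__setattr__(self, "pattern", pat)
        if not pat:
            raise ValueError("empty motif")
        bad = sorted(set(pat) - set(IUPAC_CODES))
        if bad:
            raise ValueError(f"invalid IUPAC letters in motif: {bad}")

    def __len__(self) -> int:
        return len(self.pattern)

    def reverse_complement(self) -> "IUPACMotif":
        return IUPACMotif(reverse_complement(self.pattern))

    def char_classes(self) -> list[frozenset[str]]:
        """Allowed sequence bases per position; sequence N matches only
        motif N."""
        return [
            IUPAC_CODES[c] | ({"N"} if c == "N" else set()) for c in self.pattern
        ]

    def regex(self) -> re.Pattern:
        """Overlap-reporting regex (lookahead with a capture group)."""
        body = "".join(
            "[" + "".join(sorted(cls)) + "]" for cls in self.char_classes()
        )
        return re.compile(rf"(?=({body}))")

    def expansions(self) -> list[str]:
        """All concrete A/C/G/T sequences matching the motif (N excluded)."""
        out = [""]
        for c in self.pattern:
            out = [p + b for p in out for b in sorted(IUPAC_CODES[c])]
        return out


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    offset: int  # 0-based on the promoter's forward (5'->3') coordinates
    strand: str  # '+' or '-'
    matched: str  # matched bases read 5'->3' on the hit strand


@dataclass
class PromoterSet:
    """Promoter sequences keyed by gene, 5'->3' on the coding strand.

    ``clipped`` records, per gene, how many bases were lost to a contig
    boundary (0 when the full upstream window was available).
    """

    sequences: dict[str, str]
    nominal_length: int
    clipped: dict[str, int]

    def __post_init__(self) -> None:
        for gene, seq in self.sequences.items():
            seq = seq.upper()
            self.sequences[gene] = seq
            if not _SEQ_RE.match(seq):
                raise ValueError(f"promoter of {gene} has non-ACGTN characters")
            if len(seq) > self.nominal_length:
                raise ValueError(f"promoter of {gene} exceeds nominal length")
        self.clipped = {
            g: self.clipped.get(g, self.nominal_length - len(s))
            for g, s in self.sequences.items()
        }

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, gene_id: str) -> str:
        return self.sequences[gene_id]

    def genes(self) -> list[str]:
        return list(self.sequences)


def read_promoter_fasta(path: str | Path, nominal_length: int = 1000) -> PromoterSet:
    """Read promoters from FASTA (header token = gene_id)."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate promoter FASTA entry: {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    nominal = max([nominal_length, *(len(s) for s in seqs.values())] or [nominal_length])
    return PromoterSet(seqs, nominal, {})


def write_promoter_fasta(promoters: PromoterSet, path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=gene, description="")
        for gene, seq in promoters.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def _parse_bed6(path: str | Path) -> list[tuple[str, int, int, str, str]]:
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise BedFormatError(f"{path}:{lineno}: expected >= 6 BED columns")
        chrom, start, end, name, _score, strand = parts[:6]
        try:
            start_i, end_i = int(start), int(end)
        except ValueError:
            raise BedFormatError(f"{path}:{lineno}: non-integer coordinates")
        if start_i < 0 or end_i < start_i:
            raise BedFormatError(f"{path}:{lineno}: invalid interval")
        if strand not in "+-":
            raise BedFormatError(f"{path}:{lineno}: strand must be + or -")
        rows.append((chrom, start_i, end_i, name, strand))
    return rows


def extract_promoters(
    genome_fasta: str | Path,
    bed_path: str | Path,
    upstream: int = 1000,
) -> PromoterSet:
    """Extract the ``upstream`` bp 5' of each gene's start codon.

    BED intervals are 0-based half-open with strand; the start codon sits at
    the interval start (+ strand) or interval end (- strand).  Promoters
    truncated by a contig boundary are clipped with a logged warning.
    Soft-masked (lowercase) genome bases are uppercased.
    """
    from pyfaidx import Fasta

    genome = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    seqs: dict[str, str] = {}
    clipped: dict[str, int] = {}
    for chrom, start, end, name, strand in _parse_bed6(bed_path):
        if chrom not in genome:
            raise KeyError(f"contig {chrom!r} absent from {genome_fasta}")
        contig_len = len(genome[chrom])
        if strand == "+":
            lo = max(0, start - upstream)
            seq = str(genome[chrom][lo:start])
        else:
            hi = min(contig_len, end + upstream)
            seq = reverse_complement(str(genome[chrom][end:hi]))
        if name in seqs:
            raise ValueError(f"duplicate gene name in BED: {name}")
        seqs[name] = seq
        clipped[name] = upstream - len(seq)
        if clipped[name] > 0:
            logger.warning(
                "promoter of %s clipped by %d bp at contig boundary",
                name,
                clipped[name],
            )
    return PromoterSet(seqs, upstream, clipped)


def scan_motif(
    sequence: str,
    motif: IUPACMotif,
    both_strands: bool = False,
    gene_id: str = "",
) -> list[MotifHit]:
    """All (overlapping) occurrences of the motif in a sequence.

    Reverse-strand hits carry offsets on the forward coordinate system and
    their matched substring read 5'->3' on the minus strand.  Hits are
    sorted by offset, '+' before '-'.
    """
    seq = sequence.upper()
    if not _SEQ_RE.match(seq):
        raise ValueError("sequence must be over A/C/G/T/N")
    hits = [
        MotifHit(gene_id, m.start(), "+", m.group(1))
        for m in motif.regex().finditer(seq)
    ]
    if both_strands:
        L, w = len(seq), len(motif)
        rc = reverse_complement(seq)
        for m in motif.regex().finditer(rc):
            fwd_offset = L - (m.start() + w)
            hits.append(MotifHit(gene_id, fwd_offset, "-", m.group(1)))
    return sorted(hits, key=lambda h: (h.offset, h.strand))


def genes_with_motif(
    promoters: PromoterSet,
    motif: IUPACMotif,
    both_strands: bool = True,
) -> tuple[set[str], dict[str, int]]:
    """Genes whose promoter contains >= 1 motif occurrence, plus hit counts.

    Counts include strand duplicates of palindromic matches; the presence
    set does not depend on that double-reporting.
    """
    counts: dict[str, int] = {}
    for gene in promoters.genes():
        counts[gene] = len(scan_motif(promoters[gene], motif, both_strands, gene))
    return {g for g, c in counts.items() if c > 0}, counts


def motif_enrichment(
    foreground: Iterable[str],
    background: Iterable[str],
    promoters: PromoterSet,
    motif: IUPACMotif,
    both_strands: bool = True,
) -> tuple[EnrichmentResult, Contingency2x2]:
    """Chi-squared enrichment of motif presence in a foreground gene set.

    ``foreground`` must be a proper subset of ``background``; the 2x2 table
    contrasts motif presence inside vs outside the foreground, and the fold
    is the foreground presence rate over the background-wide rate.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg <= bg:
        raise ValueError("foreground must be a subset of background")
    if fg == bg:
        raise ValueError("foreground must be a proper subset of background")
    present, _ = genes_with_motif(promoters, motif, both_strands)
    a = len(fg & present)
    b = len(fg - present)
    out = bg - fg
    c = len(out & present)
    d = len(out - present)
    table = Contingency2x2(a, b, c, d)
    return chi_squared_2x2(table), table


def write_hits_tsv(hits: Sequence[MotifHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\toffset\tstrand\tmatched\n")
        for h in hits:
            fh.write(f"{h.gene_id}\t{h.offset}\t{h.strand}\t{h.matched}\n")


def write_presence_tsv(counts: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tn_hits\n")
        for gene in sorted(counts):
            fh.write(f"{gene}\t{counts[gene]}\n")
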