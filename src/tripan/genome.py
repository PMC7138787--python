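"""Genome sequences and gene models.

A :class:`GenomeSequence` is an ordered set of named chromosomes over the
alphabet ``{A, C, G, T, N}``. A :class:`GeneModel` is a strand-aware set of
sorted, non-overlapping exon and CDS intervals; the spliced CDS of a
simulator-emitted gene is a clean ORF (ATG start, single terminal stop,
length divisible by three).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .errors import CoordinateError, ConsistencyError
from .intervals import Interval, intersect, total_bp

_ALPHABET = frozenset("ACGTN")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(cds: str) -> str:
    """Translate a CDS with the standard code; '*' marks stops."""
    return str(Seq(cds).translate())


@dataclass
class GenomeSequence:
    """An assembled genome: ordered (name, sequence) chromosomes."""

    genome_id: str
    chromosomes: list[tuple[str, str]]
    _index: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self):
        names = [name for name, _ in self.chromosomes]
        if len(names) != len(set(names)):
            raise ConsistencyError(
                f"duplicate chromosome names in genome {self.genome_id}"
            )
        for name, seq in self.chromosomes:
            extra = set(seq) - _ALPHABET
            if extra:
                raise ConsistencyError(
                    f"{self.genome_id}/{name}: alphabet outside ACGTN: {sorted(extra)}"
                )
        self._index = dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.chromosomes)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes}

    def seq(self, chrom: str) -> str:
        try:
            return self._index[chrom]
        except KeyError:
            raise ConsistencyError(
                f"unknown chromosome {chrom!r} in genome {self.genome_id}"
            ) from None

    def fetch(self, iv: Interval) -> str:
        seq = self.seq(iv.chrom)
        if iv.end > len(seq):
            raise CoordinateError(
                f"{iv.chrom}:{iv.start}-{iv.end} beyond chromosome end {len(seq)}"
            )
        return seq[iv.start : iv.end]

    def gc_fraction(self) -> float:
        gc = at = 0
        for _, seq in self.chromosomes:
            gc += seq.count("G") + seq.count("C")
            at += seq.count("A") + seq.count("T")
        return gc / (gc + at) if gc + at else 0.0


def _check_sorted_disjoint(ivs: list[Interval], what: str, gene_id: str):
    for prev, cur in zip(ivs, ivs[1:]):
        if cur.start < prev.end or cur.chrom != prev.chrom:
            raise ConsistencyError(
                f"gene {gene_id}: {what} intervals overlap or are unsorted"
            )


@dataclass
class GeneModel:
    """A protein-coding gene: sorted non-overlapping exons and CDS pieces."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ConsistencyError(f"gene {self.gene_id}: strand must be + or -")
        if not self.cds:
            raise ConsistencyError(f"gene {self.gene_id}: empty CDS")
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        _check_sorted_disjoint(self.exons, "exon", self.gene_id)
        _check_sorted_disjoint(self.cds, "CDS", self.gene_id)
        if total_bp(intersect(self.cds, self.exons)) != total_bp(self.cds):
            raise ConsistencyError(f"gene {self.gene_id}: CDS not contained in exons")

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.exons[0].start, self.exons[-1].end)

    @property
    def cds_length(self) -> int:
        return sum(iv.length for iv in self.cds)

    def coding_sequence(self, genome: GenomeSequence) -> str:
        """Spliced CDS in translation orientation (reverse-complemented for -)."""
        parts = [genome.fetch(iv) for iv in self.cds]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq

    def cds_offset(self, pos: int) -> int | None:
        """Map a genomic position to its 0-based offset in the spliced,
        strand-oriented CDS; None if the position is not coding."""
        running = 0
        pieces = self.cds if self.strand == "+" else list(reversed(self.cds))
        for iv in pieces:
            if iv.start <= pos < iv.end:
                if self.strand == "+":
                    return running + (pos - iv.start)
                return running + (iv.end - 1 - pos)
            running += iv.length
        return None
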