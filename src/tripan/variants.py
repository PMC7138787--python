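"""SNP/indel extraction, effect annotation, and structural categories.

Small variants are read directly off one-to-one alignment blocks: one SNP
per mismatched aligned column, one indel per internal gap run up to the
small-variant bound (10 bp), with alleles reported on the reference strand.

Effects follow the standard codon logic: a coding SNP is synonymous /
nonsynonymous / stop_gain / stop_loss by comparing the translated codon
before and after (strand-aware); a coding indel is a frameshift unless its
length is divisible by three (inframe). Stop codons are TAA/TAG/TGA,
standard code only. A SNP or indel causing stop gain, stop loss or a
frameshift is a *large-effect* mutation.

Variants larger than the bound are classified into six structural
categories from alignment-gap geometry. For a within-block gap the call is
insertion/deletion by which side carries the extra bases. Between
consecutive blocks, with ``dr`` the reference gap and ``dq`` the
strand-adjusted query gap:

* both >= 0, ``min(dr, dq) <= repeat_gap_min`` -> insertion/deletion;
* both >= 0, ``min(dr, dq) > repeat_gap_min`` -> repeat expansion (dq > dr)
  or contraction;
* ``dr < 0 <= dq`` (blocks overlap on the reference) -> tandem expansion;
* ``dq < 0 <= dr`` -> tandem contraction;
* both negative -> unclassified, reported separately.

These decision rules are this package's committed convention; the category
vocabulary is the field's standard assembly-vs-assembly SV typology.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .blocks import AlignmentBlock
from .config import DEFAULT_CONFIG, ThresholdConfig
from .errors import ConsistencyError, OrderingError
from .genome import GeneModel, GenomeSequence, revcomp, translate
from .intervals import Interval

EFFECTS = (
    "intergenic", "synonymous", "nonsynonymous", "stop_gain", "stop_loss",
    "frameshift", "inframe",
)
LARGE_EFFECT = frozenset({"stop_gain", "stop_loss", "frameshift"})
SV_CATEGORIES = (
    "insertion", "deletion", "repeat_expansion", "repeat_contraction",
    "tandem_expansion", "tandem_contraction",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class VariantRecord:
    chrom: str
    start: int              # 0-based; == end for insertions
    end: int
    ref_allele: str         # empty for insertions
    alt_allele: str         # empty for deletions
    vtype: str              # snp | ins | del
    effects: set[str] = field(default_factory=set)
    boundary: bool = False  # partially overlaps a CDS boundary

    def __post_init__(self):
        if self.vtype == "snp":
            ok = (len(self.ref_allele) == 1 and len(self.alt_allele) == 1
                  and self.ref_allele != self.alt_allele)
        elif self.vtype == "ins":
            ok = self.ref_allele == "" and len(self.alt_allele) > 0
        elif self.vtype == "del":
            ok = self.alt_allele == "" and len(self.ref_allele) > 0
        else:
            ok = False
        if not ok:
            raise ConsistencyError(
                f"inconsistent variant {self.vtype} {self.ref_allele}>{self.alt_allele}"
            )

    @property
    def size(self) -> int:
        return max(len(self.ref_allele), len(self.alt_allele))

    @property
    def is_large_effect(self) -> bool:
        return bool(self.effects & LARGE_EFFECT)


@dataclass(frozen=True)
class LargeVariant:
    category: str
    ref_anchor: Interval
    qry_anchor: Interval
    size: int


# -- small-variant calling --------------------------------------------------

def call_small_variants(
    blocks: list[AlignmentBlock],
    ref: GenomeSequence,
    qry: GenomeSequence,
    config: ThresholdConfig = DEFAULT_CONFIG,
) -> list[VariantRecord]:
    """SNPs and small indels from block mismatch columns and gap runs."""
    out: list[VariantRecord] = []
    for block in blocks:
        ref_seq = ref.seq(block.ref.chrom)
        qry_seq = qry.seq(block.qry.chrom)
        segs = block.segments()
        # mismatched columns inside matched spans
        for seg in segs:
            r = ref_seq[seg.ref_start : seg.ref_end]
            q = qry_seq[seg.qry_start : seg.qry_end]
            if block.strand == "-":
                q = revcomp(q)
            if r == q:
                continue
            ra = np.frombuffer(r.encode(), dtype=np.uint8)
            qa = np.frombuffer(q.encode(), dtype=np.uint8)
            for off in np.flatnonzero(ra != qa):
                pos = seg.ref_start + int(off)
                out.append(
                    VariantRecord(block.ref.chrom, pos, pos + 1,
                                  r[off], q[off], "snp")
                )
        # indels from the gap walk
        for prev, cur in zip(segs, segs[1:]):
            ref_gap = cur.ref_start - prev.ref_end
            if block.strand == "+":
                qry_lo, qry_hi = prev.qry_end, cur.qry_start
            else:
                qry_lo, qry_hi = cur.qry_end, prev.qry_start
            qry_gap = qry_hi - qry_lo
            pos = prev.ref_end
            if 0 < ref_gap <= config.small_variant_max:
                out.append(
                    VariantRecord(block.ref.chrom, pos, pos + ref_gap,
                                  ref_seq[pos : pos + ref_gap], "", "del")
                )
            if 0 < qry_gap <= config.small_variant_max:
                inserted = qry_seq[qry_lo:qry_hi]
                if block.strand == "-":
                    inserted = revcomp(inserted)
                anchor = pos + (ref_gap if 0 < ref_gap <= config.small_variant_max
                                else 0)
                out.append(
                    VariantRecord(block.ref.chrom, anchor, anchor, "",
                                  inserted, "ins")
                )
    left_align(out, ref)
    return sorted(out, key=lambda v: (v.chrom, v.start, v.vtype))


def left_align(variants: list[VariantRecord], ref: GenomeSequence) -> None:
    """Canonicalize indel placement by shifting left through repeat context
    (the usual VCF normalization), in place. SNPs are untouched."""
    for v in variants:
        if v.vtype == "snp":
            continue
        seq = ref.seq(v.chrom)
        if v.vtype == "del":
            allele, start = v.ref_allele, v.start
            while start > 0 and seq[start - 1] == allele[-1]:
                allele = seq[start - 1] + allele[:-1]
                start -= 1
            v.start, v.end, v.ref_allele = start, start + len(allele), allele
        else:
            allele, start = v.alt_allele, v.start
            while start > 0 and seq[start - 1] == allele[-1]:
                allele = seq[start - 1] + allele[:-1]
                start -= 1
            v.start = v.end = start
            v.alt_allele = allele


# -- effect annotation ------------------------------------------------------

def annotate_effects(
    variants: list[VariantRecord],
    genes: list[GeneModel],
    genome: GenomeSequence,
) -> list[VariantRecord]:
    """Fill each record's effect set against the gene models (in place).

    Positions outside coding sequence (including introns) are intergenic.
    An indel partially overlapping a CDS boundary keeps its mod-3 call but
    is flagged ``boundary``.
    """
    cds_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for gi, gene in enumerate(genes):
        for piece in gene.cds:
            cds_trees[gene.chrom].addi(piece.start, piece.end, gi)
    coding_cache: dict[str, str] = {}
    for v in variants:
        lo, hi = v.start, max(v.end, v.start + 1)
        hits = cds_trees[v.chrom].overlap(lo, hi) if v.chrom in cds_trees else ()
        if not hits:
            v.effects = {"intergenic"}
            continue
        effects: set[str] = set()
        for hit in hits:
            gene = genes[hit.data]
            if v.vtype == "snp":
                effects.add(_snp_effect(v, gene, genome, coding_cache))
            else:
                size = v.size
                effects.add("frameshift" if size % 3 else "inframe")
                if v.vtype == "del" and not (
                    hit.begin <= v.start and v.end <= hit.end
                ):
                    v.boundary = True
        v.effects = effects
    return variants


def _snp_effect(v: VariantRecord, gene: GeneModel, genome: GenomeSequence,
                cache: dict[str, str]) -> str:
    if gene.gene_id not in cache:
        cache[gene.gene_id] = gene.coding_sequence(genome)
    coding = cache[gene.gene_id]
    off = gene.cds_offset(v.start)
    if off is None:
        return "intergenic"
    alt = v.alt_allele
    if gene.strand == "-":
        alt = alt.translate(_COMPLEMENT)
    codon_i = off // 3
    codon = coding[codon_i * 3 : codon_i * 3 + 3]
    if len(codon) < 3:
        return "nonsynonymous"  # truncated terminal codon; treat as coding change
    mutated = codon[: off % 3] + alt + codon[off % 3 + 1 :]
    aa_ref, aa_alt = translate(codon), translate(mutated)
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "stop_gain"
    if aa_ref == "*":
        return "stop_loss"
    return "nonsynonymous"


# -- large (structural) variants --------------------------------------------

def _anchor(chrom: str, a: int, b: int) -> Interval:
    lo, hi = min(a, b), max(a, b)
    return Interval(chrom, lo, hi if hi > lo else hi + 1)


def classify_large_variants(
    blocks: list[AlignmentBlock],
    config: ThresholdConfig = DEFAULT_CONFIG,
) -> tuple[list[LargeVariant], list[LargeVariant]]:
    """Six-category classification; returns (classified, unclassified).

    ``blocks`` must be sorted by reference coordinate (OrderingError
    otherwise). Within-block gap runs yield insertions/deletions; the
    between-block rules are in the module docstring. Category counts over
    the six classes always sum to ``len(classified)``.
    """
    for prev, cur in zip(blocks, blocks[1:]):
        if (cur.ref.chrom, cur.ref.start) < (prev.ref.chrom, prev.ref.start):
            raise OrderingError("blocks must be sorted by reference coordinate")
    classified: list[LargeVariant] = []
    unclassified: list[LargeVariant] = []
    min_size = config.large_variant_min

    for block in blocks:
        segs = block.segments()
        for prev, cur in zip(segs, segs[1:]):
            dr = cur.ref_start - prev.ref_end
            if block.strand == "+":
                qlo, qhi = prev.qry_end, cur.qry_start
            else:
                qlo, qhi = cur.qry_end, prev.qry_start
            dq = qhi - qlo
            size = abs(dq - dr)
            if size < min_size:
                continue
            category = "insertion" if dq > dr else "deletion"
            classified.append(
                LargeVariant(category,
                             _anchor(block.ref.chrom, prev.ref_end, cur.ref_start),
                             _anchor(block.qry.chrom, qlo, qhi), size)
            )

    groups: dict[tuple, list[AlignmentBlock]] = defaultdict(list)
    for b in blocks:
        groups[(b.ref.chrom, b.qry.chrom, b.strand)].append(b)
    for (_rchrom, _qchrom, strand), group in groups.items():
        group = sorted(group, key=lambda b: (b.ref.start, b.ref.end))
        for prev, cur in zip(group, group[1:]):
            dr = cur.ref.start - prev.ref.end
            if strand == "+":
                dq = cur.qry.start - prev.qry.end
            else:
                dq = prev.qry.start - cur.qry.end
            if max(dr, dq) > config.max_bridge:
                continue  # distant blocks; not one locus
            size = abs(dq - dr)
            if size < min_size:
                continue
            ref_anchor = _anchor(prev.ref.chrom, prev.ref.end, cur.ref.start)
            if strand == "+":
                qry_anchor = _anchor(prev.qry.chrom, prev.qry.end, cur.qry.start)
            else:
                qry_anchor = _anchor(prev.qry.chrom, cur.qry.end, prev.qry.start)
            # clamp sub-k overlaps (k-mer extension noise) to zero so they do
            # not masquerade as tandem signals
            slack = config.anchor_k
            if -slack <= dr < 0:
                dr = 0
            if -slack <= dq < 0:
                dq = 0
            if dr >= 0 and dq >= 0:
                if min(dr, dq) <= config.repeat_gap_min:
                    category = "insertion" if dq > dr else "deletion"
                else:
                    category = ("repeat_expansion" if dq > dr
                                else "repeat_contraction")
            elif dr < 0 <= dq:
                category = "tandem_expansion"
            elif dq < 0 <= dr:
                category = "tandem_contraction"
            else:
                unclassified.append(
                    LargeVariant("unclassified", ref_anchor, qry_anchor, size)
                )
                continue
            classified.append(LargeVariant(category, ref_anchor, qry_anchor, size))
    classified.sort(key=lambda v: (v.ref_anchor.chrom, v.ref_anchor.start))
    return classified, unclassified


def category_counts(classified: list[LargeVariant]) -> dict[str, int]:
    counts = {c: 0 for c in SV_CATEGORIES}
    counts.update(Counter(v.category for v in classified))
    return counts


# -- indel spectrum ---------------------------------------------------------

def indel_size_spectrum(variants: list[VariantRecord],
                        stratum: str) -> dict[int, int]:
    """Signed indel-size histogram (+insertions, -deletions) per stratum.

    ``stratum='cds'`` selects indels annotated inframe/frameshift;
    ``'intergenic'`` selects purely intergenic ones. Annotate first.
    """
    if stratum not in ("cds", "intergenic"):
        raise ConsistencyError(f"unknown stratum {stratum!r}")
    spectrum: Counter[int] = Counter()
    for v in variants:
        if v.vtype == "snp":
            continue
        coding = bool(v.effects & {"frameshift", "inframe"})
        if (stratum == "cds") != coding:
            continue
        signed = v.size if v.vtype == "ins" else -v.size
        spectrum[signed] += 1
    return dict(sorted(spectrum.items()))
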