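"""Readers and writers for the standard formats the pipeline touches.

Internally everything is 0-based half-open; these functions are the single
conversion point to the 1-based inclusive conventions of FASTA-adjacent
formats (GFF3, show-coords, VCF). BED stays 0-based half-open by definition.

The "coords" dialect is the tab output of `show-coords -T -H` style tools:

    S1  E1  S2  E2  LEN1  LEN2  %IDY  refname  qryname

with 1-based inclusive columns and reverse-strand query rows encoded as
``S2 > E2``.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .blocks import AlignmentBlock
from .errors import ParseError
from .genome import GeneModel, GenomeSequence
from .intervals import Interval


# -- FASTA ------------------------------------------------------------------

def write_fasta(genome: GenomeSequence, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chromosomes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike, genome_id: str | None = None) -> GenomeSequence:
    chroms = [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if genome_id is None:
        genome_id = os.path.splitext(os.path.basename(str(path)))[0]
    return GenomeSequence(genome_id=genome_id, chromosomes=chroms)


# -- GFF3 subset ------------------------------------------------------------

def write_gff3(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """gene/mRNA/exon/CDS features with ID=/Parent= attributes only."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            span = gene.span
            base = (gene.chrom, "tripan", "%s", span.start + 1, span.end, ".",
                    gene.strand, ".")
            fh.write(
                "\t".join(map(str, base)) % "gene"
                + f"\tID={gene.gene_id}\n"
            )
            mrna_id = f"{gene.gene_id}.t1"
            fh.write(
                "\t".join(map(str, base)) % "mRNA"
                + f"\tID={mrna_id};Parent={gene.gene_id}\n"
            )
            for i, iv in enumerate(gene.exons, 1):
                fh.write(
                    f"{gene.chrom}\ttripan\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{gene.strand}\t.\tID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
            for i, iv in enumerate(gene.cds, 1):
                fh.write(
                    f"{gene.chrom}\ttripan\tCDS\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{gene.strand}\t.\tID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )


def _gff_attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if part and "=" in part:
            key, value = part.split("=", 1)
            out[key] = value
    return out


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Read the gene/mRNA/exon/CDS subset written by :func:`write_gff3`."""
    genes: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"expected 9 GFF columns, got {len(fields)}", lineno)
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            try:
                iv = Interval(chrom, int(start) - 1, int(end))
            except ValueError:
                raise ParseError("non-integer coordinates", lineno) from None
            attr = _gff_attrs(attrs)
            if ftype == "gene":
                gid = attr.get("ID")
                if gid is None:
                    raise ParseError("gene feature without ID=", lineno)
                genes[gid] = {"chrom": chrom, "strand": strand,
                              "exons": [], "cds": []}
                order.append(gid)
            elif ftype == "mRNA":
                mrna_to_gene[attr.get("ID", "")] = attr.get("Parent", "")
            elif ftype in ("exon", "CDS"):
                parent = attr.get("Parent", "")
                gid = mrna_to_gene.get(parent, parent)
                if gid not in genes:
                    raise ParseError(f"{ftype} with unknown parent {parent!r}", lineno)
                key = "exons" if ftype == "exon" else "cds"
                genes[gid][key].append(iv)
    out = []
    for gid in order:
        info = genes[gid]
        exons = info["exons"] or list(info["cds"])
        out.append(GeneModel(gene_id=gid, chrom=info["chrom"],
                             strand=info["strand"], exons=exons, cds=info["cds"]))
    return out


# -- show-coords tab dialect ------------------------------------------------

def write_coords(blocks: Iterable[AlignmentBlock], path: str | os.PathLike) -> None:
    """One row per block; internal gap structure is not representable here
    (split blocks at large gaps first if coverage semantics matter)."""
    with open(path, "w") as fh:
        for b in blocks:
            s1, e1 = b.ref.start + 1, b.ref.end
            if b.strand == "+":
                s2, e2 = b.qry.start + 1, b.qry.end
            else:
                s2, e2 = b.qry.end, b.qry.start + 1
            fh.write(
                f"{s1}\t{e1}\t{s2}\t{e2}\t{b.ref.length}\t{b.qry.length}\t"
                f"{b.identity * 100:.2f}\t{b.ref.chrom}\t{b.qry.chrom}\n"
            )


def read_coords(path: str | os.PathLike) -> list[AlignmentBlock]:
    blocks = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"expected >= 9 columns, got {len(fields)}", lineno)
            try:
                s1, e1, s2, e2 = (int(x) for x in fields[:4])
                idy = float(fields[6])
            except ValueError:
                raise ParseError("non-numeric coordinate column", lineno) from None
            ref_name, qry_name = fields[7], fields[8]
            if s1 > e1:
                raise ParseError("reference coordinates reversed", lineno)
            strand = "+" if s2 <= e2 else "-"
            if strand == "-":
                s2, e2 = e2, s2
            try:
                ref = Interval(ref_name, s1 - 1, e1)
                qry = Interval(qry_name, s2 - 1, e2)
            except Exception as exc:
                raise ParseError(str(exc), lineno) from None
            ref_span, qry_span = ref.length, qry.length
            # A gapless row can only be square; pad one side with a single
            # terminal gap record so the block invariant holds.
            gaps = []
            if ref_span > qry_span:
                gaps = [(ref_span - (ref_span - qry_span), ref_span - qry_span, 0)]
            elif qry_span > ref_span:
                gaps = [(ref_span, 0, qry_span - ref_span)]
            blocks.append(
                AlignmentBlock(ref=ref, qry=qry, strand=strand,
                               identity=round(idy / 100.0, 6), gaps=gaps)
            )
    return blocks


# -- BED --------------------------------------------------------------------

def write_bed(
    rows: Iterable[tuple],
    path: str | os.PathLike,
) -> None:
    """Write BED rows; each row is (Interval, *extra_columns)."""
    with open(path, "w") as fh:
        for row in rows:
            iv, *extra = row
            cols = [iv.chrom, str(iv.start), str(iv.end)] + [str(x) for x in extra]
            fh.write("\t".join(cols) + "\n")


def read_bed_depth(path: str | os.PathLike) -> list[tuple[Interval, float]]:
    """Read a BED4 depth track: chrom, start, end, mean depth."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError("expected BED4 (chrom start end depth)", lineno)
            try:
                iv = Interval(fields[0], int(fields[1]), int(fields[2]))
                depth = float(fields[3])
            except ValueError:
                raise ParseError("non-numeric BED column", lineno) from None
            out.append((iv, depth))
    return out


# -- VCF --------------------------------------------------------------------

def write_vcf(variants, genome: GenomeSequence, path: str | os.PathLike) -> None:
    """Minimal VCF 4.2: CHROM POS ID REF ALT QUAL FILTER INFO(EFF=...).

    Indels are left-padded with the reference base before POS, as VCF
    requires non-empty alleles.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=EFF,Number=.,Type=String,Description="Effects">\n')
        for name, length in genome.chrom_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            if v.vtype == "snp":
                pos = v.start + 1
                ref_allele, alt_allele = v.ref_allele, v.alt_allele
            else:
                anchor_pos = max(v.start - 1, 0)
                anchor = genome.seq(v.chrom)[anchor_pos]
                pos = anchor_pos + 1
                ref_allele = anchor + v.ref_allele
                alt_allele = anchor + v.alt_allele
            info = "EFF=" + ",".join(sorted(v.effects)) if v.effects else "."
            fh.write(
                f"{v.chrom}\t{pos}\t.\t{ref_allele}\t{alt_allele}\t.\tPASS\t{info}\n"
            )
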