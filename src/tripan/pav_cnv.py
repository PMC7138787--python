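"""Presence-absence variation and copy-number variation calling.

PAV, four classes between a query and a reference genome: sequence present
in the query but absent from the reference is found as query intervals with
no one-to-one alignment coverage, re-searched against the reference, and
kept only when the best realignment identity is at or below the identity
bound (or there is no hit at all) — segments longer than 100 bp with a
< 95%-identity best hit, in the default configuration. Sequence absent from
the query is found as uncovered reference intervals, merged across < 500 bp
gaps. Genes are attached by CDS-coverage fractions.

CNV: windows of a normalized read-depth track outside the loss/gain ratio
bounds are merged into runs; runs of at least 500 bp become CNV regions.
Calls are invariant under uniform depth rescaling because only the ratio to
the genome mean enters. Genes with more than 80% of exon bp inside CNV
regions are the candidate CNV-affected genes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import align_genomes
from .blocks import AlignmentBlock
from .config import DEFAULT_CONFIG, ThresholdConfig
from .errors import ConsistencyError, InputError
from .genome import GeneModel, GenomeSequence
from .intervals import (
    Interval, complement, covered_fraction, intersect, merge_intervals,
    total_bp,
)
from .simulate import DepthTrack


@dataclass(frozen=True)
class PavRecord:
    klass: str                      # RS10 | RS01 | NS10 | NS01 (or caller label)
    interval: Interval              # on the genome where the sequence exists
    length: int
    best_realignment_identity: float | None

    def __post_init__(self):
        if self.length != self.interval.length:
            raise ConsistencyError("PAV length disagrees with its interval")


@dataclass(frozen=True)
class CnvRegion:
    interval: Interval
    norm_depth: float               # fold of the genome mean
    call: str                       # gain | loss


@dataclass(frozen=True)
class GeneCnvCall:
    gene_id: str
    call: str                       # gain | loss | both | none


def _qry_coverage(blocks: list[AlignmentBlock], gap: int) -> list[Interval]:
    ivs: list[Interval] = []
    for b in blocks:
        ivs.extend(b.qry_aligned_intervals(gap))
    return merge_intervals(ivs, 0) if ivs else []


def _ref_coverage(blocks: list[AlignmentBlock], gap: int) -> list[Interval]:
    ivs: list[Interval] = []
    for b in blocks:
        ivs.extend(b.ref_aligned_intervals(gap))
    return merge_intervals(ivs, 0) if ivs else []


# -- presence in query (RS10 / NS10) ---------------------------------------

def call_pav_present_in_query(
    qry: GenomeSequence,
    qry_to_ref: list[AlignmentBlock],
    ref: GenomeSequence,
    config: ThresholdConfig = DEFAULT_CONFIG,
    klass: str = "RS10",
    genes: list[GeneModel] | None = None,
) -> tuple[list[PavRecord], list[str]]:
    """Query sequence with no credible home in the reference.

    Uncovered query intervals longer than the PAV bound are realigned
    against the whole reference with the anchor aligner; survivors whose
    best-hit identity exceeds the identity bound are discarded (they are
    merely diverged or duplicated copies, not presence/absence). Also
    returns IDs of query genes with more than the specific-gene CDS
    fraction inside PAV intervals.
    """
    covered = _qry_coverage(qry_to_ref, config.small_variant_max)
    uncovered = complement(covered, qry.chrom_lengths)
    candidates = [iv for iv in uncovered if iv.length > config.pav_min_len]
    records: list[PavRecord] = []
    if candidates:
        probe = GenomeSequence(
            genome_id=f"{qry.genome_id}_pav_probe",
            chromosomes=[
                (f"cand{i}", qry.fetch(iv)) for i, iv in enumerate(candidates)
            ],
        )
        hits = align_genomes(probe, ref, config, mode="collinear")
        best: dict[str, float] = {}
        for b in hits:
            best[b.ref.chrom] = max(best.get(b.ref.chrom, 0.0), b.identity)
        for i, iv in enumerate(candidates):
            identity = best.get(f"cand{i}")
            if identity is None or identity <= config.pav_max_identity:
                records.append(PavRecord(klass, iv, iv.length, identity))
    gene_ids: list[str] = []
    if genes:
        pav_ivs = [r.interval for r in records]
        for gene in genes:
            if pav_ivs and covered_fraction(gene.cds, pav_ivs) > \
                    config.pav_specific_gene_cds_frac:
                gene_ids.append(gene.gene_id)
    return records, gene_ids


# -- absence in query (RS01 / NS01) ----------------------------------------

def call_pav_absent_in_query(
    ref: GenomeSequence,
    qry_to_ref: list[AlignmentBlock],
    config: ThresholdConfig = DEFAULT_CONFIG,
    klass: str = "RS01",
    genes: list[GeneModel] | None = None,
) -> tuple[list[PavRecord], list[str]]:
    """Reference sequence the query has lost.

    Reference intervals with zero query coverage are merged across gaps
    smaller than the merge bound and reported when longer than the PAV
    bound. Reference genes with at least the absence CDS fraction inside
    these blocks are reported as reference-specific relative to the query.
    """
    covered = _ref_coverage(qry_to_ref, config.small_variant_max)
    uncovered = complement(covered, ref.chrom_lengths)
    merged = merge_intervals(uncovered, config.pav_merge_gap) if uncovered else []
    records = [
        PavRecord(klass, iv, iv.length, None)
        for iv in merged
        if iv.length > config.pav_min_len
    ]
    gene_ids: list[str] = []
    if genes:
        pav_ivs = [r.interval for r in records]
        for gene in genes:
            if pav_ivs and covered_fraction(gene.cds, pav_ivs) >= \
                    config.pav_gene_cds_frac:
                gene_ids.append(gene.gene_id)
    return records, gene_ids


# -- copy-number variation --------------------------------------------------

def call_cnv(depth: DepthTrack,
             config: ThresholdConfig = DEFAULT_CONFIG) -> list[CnvRegion]:
    """Runs of depth-ratio outliers at least ``cnv_min_len`` long."""
    if not depth.windows:
        raise InputError("empty depth track")
    total = sum(iv.length for iv, _ in depth.windows)
    mean = sum(d * iv.length for iv, d in depth.windows) / total
    if mean <= 0:
        raise InputError("zero mean depth")
    regions: list[CnvRegion] = []
    run: list[tuple[Interval, float]] = []
    run_call = None

    def flush():
        nonlocal run, run_call
        if run:
            span = Interval(run[0][0].chrom, run[0][0].start, run[-1][0].end)
            if span.length >= config.cnv_min_len:
                bp = sum(iv.length for iv, _ in run)
                norm = sum(nd * iv.length for iv, nd in run) / bp
                regions.append(CnvRegion(span, norm, run_call))
        run, run_call = [], None

    for iv, d in depth.windows:
        norm = d / mean
        call = ("loss" if norm < config.cnv_low
                else "gain" if norm > config.cnv_high else None)
        contiguous = bool(run) and run[-1][0].chrom == iv.chrom \
            and run[-1][0].end == iv.start
        if call is None or call != run_call or not contiguous:
            flush()
        if call is not None:
            run.append((iv, norm))
            run_call = call
    flush()
    return regions


def classify_cnv_genes(
    genes: list[GeneModel],
    cnv_regions: list[CnvRegion],
    config: ThresholdConfig = DEFAULT_CONFIG,
) -> list[GeneCnvCall]:
    """Gene-level gain/loss/both calls by exon-bp coverage.

    A gene is affected when more than ``cnv_gene_exon_frac`` of its exon bp
    lies inside CNV regions (union of both directions); the direction is
    'both' when gain and loss regions each overlap its exons.
    """
    gains = [r.interval for r in cnv_regions if r.call == "gain"]
    losses = [r.interval for r in cnv_regions if r.call == "loss"]
    out: list[GeneCnvCall] = []
    for gene in genes:
        union = merge_intervals(gains + losses, 0) if gains or losses else []
        frac = covered_fraction(gene.exons, union) if union else 0.0
        if frac <= config.cnv_gene_exon_frac:
            out.append(GeneCnvCall(gene.gene_id, "none"))
            continue
        has_gain = bool(gains) and total_bp(intersect(gene.exons, gains)) > 0
        has_loss = bool(losses) and total_bp(intersect(gene.exons, losses)) > 0
        if has_gain and has_loss:
            call = "both"
        elif has_gain:
            call = "gain"
        elif has_loss:
            call = "loss"
        else:
            call = "none"
        out.append(GeneCnvCall(gene.gene_id, call))
    return out
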