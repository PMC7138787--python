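"""Truth-recovery scoring against simulator truth sets.

Small-variant comparisons are exact on (chromosome, position, alleles)
after left-alignment of indels on both sides; variants within a buffer of a
planted structural event are excluded from precision/recall (breakpoint
placement there is alignment-convention, not caller quality). Structural,
PAV and CNV events are matched by locus overlap with tolerances bounded by
anchor granularity.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .genome import GenomeSequence
from .intervals import Interval
from .pav_cnv import CnvRegion, PavRecord
from .simulate import TruthSet
from .variants import LargeVariant, VariantRecord, left_align

SV_BUFFER = 100  # bp around structural events excluded from small-variant scoring


def truth_small_variants(truth: TruthSet,
                         ancestor: GenomeSequence) -> list[VariantRecord]:
    """Planted SNPs/indels as left-aligned records on ancestor coordinates."""
    records = []
    for e in truth.by_type("snp"):
        records.append(
            VariantRecord(e.chrom, e.donor_start, e.donor_end, e.ref, e.seq, "snp")
        )
    for e in truth.by_type("ins"):
        records.append(
            VariantRecord(e.chrom, e.donor_start, e.donor_start, "", e.seq, "ins")
        )
    for e in truth.by_type("del"):
        records.append(
            VariantRecord(e.chrom, e.donor_start, e.donor_end, e.ref, "", "del")
        )
    left_align(records, ancestor)
    return records


def _sv_zones(truth: TruthSet, buffer: int = SV_BUFFER) -> list[Interval]:
    zones = []
    for e in truth.by_type("pav_gain", "pav_loss", "cnv_gain", "cnv_loss"):
        zones.append(
            Interval(e.chrom, max(0, e.donor_start - buffer), e.donor_end + buffer)
        )
    return zones


def _keys(records: Sequence[VariantRecord], zones: Sequence[Interval]):
    out = set()
    for v in records:
        iv = Interval(v.chrom, v.start, max(v.end, v.start + 1))
        if any(iv.overlaps(z) for z in zones):
            continue
        out.add((v.chrom, v.start, v.vtype, v.ref_allele, v.alt_allele))
    return out


def small_variant_scores(
    called: Sequence[VariantRecord],
    truth: TruthSet,
    ancestor: GenomeSequence,
    vtypes: tuple[str, ...] = ("snp",),
) -> dict[str, float]:
    """Precision/recall of exact-match calls outside SV breakpoint zones."""
    zones = _sv_zones(truth)
    truth_keys = {
        k for k in _keys(truth_small_variants(truth, ancestor), zones)
        if k[2] in vtypes
    }
    called_keys = {k for k in _keys(called, zones) if k[2] in vtypes}
    tp = len(called_keys & truth_keys)
    precision = tp / len(called_keys) if called_keys else 1.0
    recall = tp / len(truth_keys) if truth_keys else 1.0
    return {"precision": precision, "recall": recall,
            "n_truth": len(truth_keys), "n_called": len(called_keys)}


# -- structural variants ----------------------------------------------------

def expected_large_variants(
    ref_truth: TruthSet, qry_truth: TruthSet
) -> list[tuple[str, Interval]]:
    """Expected category and reference-coordinate locus for each planted
    structural event when aligning ref_truth's genome against qry_truth's.

    A tandem gain on the reference side means the query has fewer copies
    (tandem_contraction); a gain on the query side is a tandem_expansion;
    query segmental insertions/deletions are plain insertions/deletions.
    The locus spans the event's full reference footprint.
    """

    def lift_iv(chrom: str, start: int, end: int) -> Interval:
        a = ref_truth.lift(chrom, start)
        b = ref_truth.lift(chrom, end)
        return Interval(chrom, min(a, b), max(a, b) + 1)

    out = []
    for e in ref_truth.by_type("cnv_gain"):
        out.append(("tandem_contraction",
                    lift_iv(e.chrom, e.donor_start,
                            e.donor_end + (e.copies - 1) * e.donor_span)))
    for e in qry_truth.by_type("cnv_gain"):
        out.append(("tandem_expansion",
                    lift_iv(e.chrom, e.donor_start, e.donor_end)))
    for e in qry_truth.by_type("pav_gain"):
        out.append(("insertion", lift_iv(e.chrom, e.donor_start,
                                         e.donor_start + 1)))
    for e in qry_truth.by_type("pav_loss"):
        out.append(("deletion", lift_iv(e.chrom, e.donor_start, e.donor_end)))
    return out


def sv_category_scores(
    classified: Sequence[LargeVariant],
    expected: Sequence[tuple[str, Interval]],
    tolerance: int = 50,
) -> dict[str, float]:
    """Fraction of planted SVs whose called category matches at the locus."""
    hits = 0
    for category, locus in expected:
        widened = Interval(locus.chrom, max(0, locus.start - tolerance),
                           locus.end + tolerance)
        if any(v.category == category and v.ref_anchor.overlaps(widened)
               for v in classified):
            hits += 1
    return {"correct": hits, "total": len(expected),
            "accuracy": hits / len(expected) if expected else 1.0}


# -- PAV --------------------------------------------------------------------

def pav_recovery(
    records: Sequence[PavRecord],
    expected: Sequence[Interval],
    tolerance: int = 50,
) -> dict[str, float]:
    """Planted segments recovered with both breakpoints within tolerance."""
    hits = 0
    for iv in expected:
        if any(
            r.interval.chrom == iv.chrom
            and abs(r.interval.start - iv.start) <= tolerance
            and abs(r.interval.end - iv.end) <= tolerance
            for r in records
        ):
            hits += 1
    return {"recovered": hits, "total": len(expected),
            "recall": hits / len(expected) if expected else 1.0}


# -- CNV --------------------------------------------------------------------

def cnv_scores(
    regions: Sequence[CnvRegion],
    truth: TruthSet,
    min_len: int = 0,
) -> dict[str, float]:
    """Precision/recall by direction-aware reciprocal overlap >= 0.5."""
    expected = []
    for e in truth.by_type("cnv_gain"):
        if e.donor_span >= min_len:
            expected.append(("gain", Interval(e.chrom, e.donor_start, e.donor_end)))
    for e in truth.by_type("cnv_loss"):
        if e.donor_span >= min_len:
            expected.append(("loss", Interval(e.chrom, e.donor_start, e.donor_end)))

    def reciprocal(a: Interval, b: Interval) -> float:
        inter = a.intersection_bp(b)
        return min(inter / a.length, inter / b.length) if inter else 0.0

    matched_truth = set()
    matched_called = set()
    for ti, (call, iv) in enumerate(expected):
        for ci, region in enumerate(regions):
            if region.call == call and reciprocal(region.interval, iv) >= 0.5:
                matched_truth.add(ti)
                matched_called.add(ci)
    recall = len(matched_truth) / len(expected) if expected else 1.0
    precision = len(matched_called) / len(regions) if regions else 1.0
    return {"precision": precision, "recall": recall,
            "n_truth": len(expected), "n_called": len(regions)}


# -- pan-genome truth -------------------------------------------------------

def pan_truth(
    ancestor: GenomeSequence,
    truths: Mapping[str, TruthSet],
) -> dict[str, float]:
    """Ground-truth core/dispensable/specific bp for a star-phylogeny trio.

    Each ancestor base is present in a descendant unless a segmental
    deletion removed it; bases present in all three are core, in exactly
    two dispensable, in one specific. Novel insertions (segmental gains)
    are specific to their genome.
    """
    names = list(truths)
    core = disp = 0
    specific = {g: 0 for g in names}
    for chrom, length in ancestor.chrom_lengths.items():
        present = np.ones((len(names), length), dtype=bool)
        for gi, g in enumerate(names):
            for iv in truths[g].deleted_intervals():
                if iv.chrom == chrom:
                    present[gi, iv.start : iv.end] = False
        counts = present.sum(axis=0)
        core += int((counts == 3).sum())
        disp += int((counts == 2).sum())
        for gi, g in enumerate(names):
            specific[g] += int((present[gi] & (counts == 1)).sum())
    for g in names:
        specific[g] += sum(
            len(e.seq) for e in truths[g].by_type("pav_gain")
        )
    out: dict[str, float] = {"core_bp": core, "dispensable_bp": disp}
    for g in names:
        out[f"specific_bp_{g}"] = specific[g]
    out["pan_bp"] = core + disp + sum(specific.values())
    return out
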