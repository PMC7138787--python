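"""Tri-genome pan-genome classification.

Given the three pairwise one-to-one alignment sets (pivot<->A, pivot<->B,
A<->B), every base of every genome is labeled:

* **core** — aligned to both other genomes,
* **dispensable** — aligned to exactly one,
* **specific** — aligned to neither.

Pan-genome size is reference-centric with the pivot genome (the cultivated
reference in the original comparison) as coordinate anchor: it counts the
whole pivot, plus A bases unaligned to the pivot, plus B bases unaligned to
both. B sequence that is absent from the pivot but shared with A is owned by
A, so every pan base is counted exactly once and
``pan = core + dispensable + sum(specific)`` holds exactly.

"Aligned" coverage excludes within-block gap spans longer than the small
variant bound, so a 2 kb deletion inside one block is still an absence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .blocks import AlignmentBlock
from .config import DEFAULT_CONFIG, ThresholdConfig
from .errors import ConsistencyError, UndefinedFractionError
from .genome import GeneModel
from .intervals import (
    Interval, complement, covered_fraction, intersect, merge_intervals,
    subtract, total_bp,
)
from .stats import round_half_up

KLASSES = ("core", "dispensable", "specific")


@dataclass(frozen=True)
class PanSegment:
    owner: str
    interval: Interval
    presence: tuple[bool, bool, bool]  # ordered as the names given at build
    klass: str

    def __post_init__(self):
        n = sum(self.presence)
        expected = {3: "core", 2: "dispensable", 1: "specific"}.get(n)
        if expected != self.klass:
            raise ConsistencyError(
                f"presence mask {self.presence} inconsistent with {self.klass}"
            )


@dataclass
class PanStats:
    names: tuple[str, str, str]          # (pivot, a, b)
    pan_bp: int
    core_bp: int
    dispensable_bp: int
    specific_bp: dict[str, int]
    genome_bp: dict[str, int]
    pairwise_pan_bp: dict[tuple[str, str], int]
    gene_counts: dict[str, int] | None = None

    def __post_init__(self):
        total = self.core_bp + self.dispensable_bp + sum(self.specific_bp.values())
        if total != self.pan_bp:
            raise ConsistencyError(
                f"pan additivity violated: {total} != {self.pan_bp}"
            )


@dataclass(frozen=True)
class GeneMembership:
    gene_id: str
    owner: str
    presence: dict[str, bool]
    klass: str


# -- coverage helpers -------------------------------------------------------

def _ref_cov(blocks: Sequence[AlignmentBlock], max_gap: int) -> list[Interval]:
    out: list[Interval] = []
    for b in blocks:
        out.extend(b.ref_aligned_intervals(max_gap))
    return merge_intervals(out, 0) if out else []


def _qry_cov(blocks: Sequence[AlignmentBlock], max_gap: int) -> list[Interval]:
    out: list[Interval] = []
    for b in blocks:
        out.extend(b.qry_aligned_intervals(max_gap))
    return merge_intervals(out, 0) if out else []


def _check_blocks(blocks: Sequence[AlignmentBlock],
                  ref_lengths: Mapping[str, int],
                  qry_lengths: Mapping[str, int], label: str):
    for b in blocks:
        if b.ref.chrom not in ref_lengths or b.ref.end > ref_lengths[b.ref.chrom]:
            raise ConsistencyError(
                f"{label}: reference block {b.ref} exceeds genome bounds"
            )
        if b.qry.chrom not in qry_lengths or b.qry.end > qry_lengths[b.qry.chrom]:
            raise ConsistencyError(
                f"{label}: query block {b.qry} exceeds genome bounds"
            )


# -- main construction ------------------------------------------------------

def build_pangenome(
    sat_ruf: Sequence[AlignmentBlock],
    sat_niv: Sequence[AlignmentBlock],
    ruf_niv: Sequence[AlignmentBlock],
    genome_lengths: Mapping[str, Mapping[str, int]],
    names: tuple[str, str, str] = ("SAT", "RUF", "NIV"),
    config: ThresholdConfig = DEFAULT_CONFIG,
) -> tuple[list[PanSegment], PanStats]:
    """Classify all three genomes from one-to-one block sets.

    ``sat_ruf`` and ``sat_niv`` must carry the pivot genome on their
    reference side; ``ruf_niv`` carries A as reference and B as query.
    ``genome_lengths`` maps genome name -> chromosome lengths.
    """
    pivot, a_name, b_name = names
    for name in names:
        if name not in genome_lengths:
            raise ConsistencyError(f"missing genome lengths for {name}")
    _check_blocks(sat_ruf, genome_lengths[pivot], genome_lengths[a_name], "pivot-A")
    _check_blocks(sat_niv, genome_lengths[pivot], genome_lengths[b_name], "pivot-B")
    _check_blocks(ruf_niv, genome_lengths[a_name], genome_lengths[b_name], "A-B")
    gap = config.small_variant_max

    # per-genome coverage by each partner
    cov = {
        pivot: {a_name: _ref_cov(sat_ruf, gap), b_name: _ref_cov(sat_niv, gap)},
        a_name: {pivot: _qry_cov(sat_ruf, gap), b_name: _ref_cov(ruf_niv, gap)},
        b_name: {pivot: _qry_cov(sat_niv, gap), a_name: _qry_cov(ruf_niv, gap)},
    }

    segments: list[PanSegment] = []
    per_genome: dict[str, dict[str, list[Interval]]] = {}
    for g in names:
        partners = [h for h in names if h != g]
        c1, c2 = cov[g][partners[0]], cov[g][partners[1]]
        core = intersect(c1, c2)
        disp1 = subtract(c1, c2)   # aligned to partner[0] only
        disp2 = subtract(c2, c1)
        both = merge_intervals(c1 + c2, 0) if (c1 or c2) else []
        spec = complement(both, genome_lengths[g])
        per_genome[g] = {
            "core": core, "disp_" + partners[0]: disp1,
            "disp_" + partners[1]: disp2, "spec": spec,
        }

        def mask(present: set[str]) -> tuple[bool, bool, bool]:
            return tuple(n in present for n in names)  # type: ignore[return-value]

        for iv in core:
            segments.append(PanSegment(g, iv, mask(set(names)), "core"))
        for iv in disp1:
            segments.append(PanSegment(g, iv, mask({g, partners[0]}),
                                       "dispensable"))
        for iv in disp2:
            segments.append(PanSegment(g, iv, mask({g, partners[1]}),
                                       "dispensable"))
        for iv in spec:
            segments.append(PanSegment(g, iv, mask({g}), "specific"))

    # ownership-deduplicated pan statistics (pivot-centric)
    pivot_len = sum(genome_lengths[pivot].values())
    a_len = sum(genome_lengths[a_name].values())
    b_len = sum(genome_lengths[b_name].values())
    a_unaligned = complement(cov[a_name][pivot], genome_lengths[a_name])
    b_unaligned_both = complement(
        merge_intervals(cov[b_name][pivot] + cov[b_name][a_name], 0)
        if (cov[b_name][pivot] or cov[b_name][a_name]) else [],
        genome_lengths[b_name],
    )
    core_bp = total_bp(per_genome[pivot]["core"])
    disp_bp = (
        total_bp(per_genome[pivot]["disp_" + a_name])
        + total_bp(per_genome[pivot]["disp_" + b_name])
        + total_bp(intersect(a_unaligned, cov[a_name][b_name]))
    )
    specific_bp = {
        pivot: total_bp(per_genome[pivot]["spec"]),
        a_name: total_bp(subtract(a_unaligned, cov[a_name][b_name])),
        b_name: total_bp(b_unaligned_both),
    }
    pan_bp = pivot_len + total_bp(a_unaligned) + total_bp(b_unaligned_both)
    pairwise = {
        (pivot, a_name): pivot_len
        + total_bp(complement(cov[a_name][pivot], genome_lengths[a_name])),
        (pivot, b_name): pivot_len
        + total_bp(complement(cov[b_name][pivot], genome_lengths[b_name])),
        (a_name, b_name): a_len
        + total_bp(complement(cov[b_name][a_name], genome_lengths[b_name])),
    }
    stats = PanStats(
        names=names, pan_bp=pan_bp, core_bp=core_bp, dispensable_bp=disp_bp,
        specific_bp=specific_bp,
        genome_bp={pivot: pivot_len, a_name: a_len, b_name: b_len},
        pairwise_pan_bp=pairwise,
    )
    return segments, stats


# -- gene membership --------------------------------------------------------

def classify_gene_membership(
    genes_by_genome: Mapping[str, Sequence[GeneModel]],
    segments: Sequence[PanSegment],
    names: tuple[str, str, str] = ("SAT", "RUF", "NIV"),
    presence_frac: float = 0.8,
) -> list[GeneMembership]:
    """Label each gene core/dispensable/specific by CDS coverage.

    A gene is *present* in another genome when at least ``presence_frac`` of
    its CDS bp lies inside own-genome segments whose presence mask includes
    that genome. Presence in the owner genome is definitional.
    """
    by_owner: dict[str, dict[str, list[Interval]]] = {
        g: {h: [] for h in names} for g in names
    }
    for seg in segments:
        for h, bit in zip(names, seg.presence):
            if bit and h != seg.owner:
                by_owner[seg.owner][h].append(seg.interval)
    out: list[GeneMembership] = []
    for owner, genes in genes_by_genome.items():
        if owner not in by_owner:
            raise ConsistencyError(f"unknown genome {owner!r} in gene table")
        merged = {
            h: merge_intervals(ivs, 0) if ivs else []
            for h, ivs in by_owner[owner].items()
        }
        for gene in genes:
            presence = {owner: True}
            for h in names:
                if h == owner:
                    continue
                frac = covered_fraction(gene.cds, merged[h]) if merged[h] else 0.0
                presence[h] = frac >= presence_frac
            count = sum(presence.values())
            klass = {3: "core", 2: "dispensable", 1: "specific"}[count]
            out.append(GeneMembership(gene.gene_id, owner, presence, klass))
    return out


def gene_class_counts(memberships: Sequence[GeneMembership]) -> dict[str, int]:
    counts = {k: 0 for k in KLASSES}
    for m in memberships:
        counts[m.klass] += 1
    return counts


# -- summary fractions ------------------------------------------------------

def pan_fractions(stats: PanStats) -> dict[str, float]:
    """Headline percentages, rounded half-up to 0.1%.

    ``core_pct``: core bp over pan bp. ``two_genome_avg_pct``: mean of the
    three two-genome union sizes over pan bp. Gene-class percentages are
    included when gene counts were attached to the stats.
    """
    if stats.pan_bp == 0:
        raise UndefinedFractionError("pan-genome size is zero")
    two_avg = sum(stats.pairwise_pan_bp.values()) / len(stats.pairwise_pan_bp)
    out = {
        "core_pct": round_half_up(100.0 * stats.core_bp / stats.pan_bp, 1),
        "two_genome_avg_pct": round_half_up(100.0 * two_avg / stats.pan_bp, 1),
    }
    if stats.gene_counts:
        total = sum(stats.gene_counts.values())
        if total:
            for klass, n in stats.gene_counts.items():
                out[f"{klass}_gene_pct"] = round_half_up(100.0 * n / total, 1)
    return out
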