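"""Pairwise alignment blocks.

An :class:`AlignmentBlock` is one aligned segment between a reference and a
query genome. Both coordinate intervals are stored ascending; ``strand='-'``
means the reference walks left-to-right while the query walks right-to-left
(reverse complement). Internal indels are carried as ``gaps``: an ordered
list of ``(ref_offset, ref_gap_len, qry_gap_len)`` where ``ref_offset`` is
the distance from ``ref.start`` (in reference coordinates) at which the
event sits, ``ref_gap_len`` counts reference bases with no query counterpart
(a deletion in the query) and ``qry_gap_len`` counts query bases with no
reference counterpart (an insertion in the query).

Length bookkeeping: ``ref.length + sum(qry_gap) == qry.length + sum(ref_gap)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConsistencyError
from .intervals import Interval, subtract


@dataclass(frozen=True)
class Segment:
    """A colinear, equal-length matched span (may contain mismatches)."""

    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class AlignmentBlock:
    ref: Interval
    qry: Interval
    strand: str
    identity: float
    gaps: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ConsistencyError("block strand must be + or -")
        if not 0.0 <= self.identity <= 1.0:
            raise ConsistencyError(f"identity {self.identity} outside [0, 1]")
        self.gaps = sorted(self.gaps)
        ref_gap = sum(g[1] for g in self.gaps)
        qry_gap = sum(g[2] for g in self.gaps)
        if self.ref.length + qry_gap != self.qry.length + ref_gap:
            raise ConsistencyError(
                "block length bookkeeping violated: "
                f"ref {self.ref.length} + qry_gaps {qry_gap} != "
                f"qry {self.qry.length} + ref_gaps {ref_gap}"
            )

    # -- correspondence walk ------------------------------------------------

    def segments(self) -> list[Segment]:
        """Matched spans in reference order (query spans ascending coords)."""
        segs: list[Segment] = []
        r = self.ref.start
        q = self.qry.start if self.strand == "+" else self.qry.end
        for off, ref_gap, qry_gap in self.gaps:
            pos = self.ref.start + off
            m = pos - r
            if m < 0:
                raise ConsistencyError("gap offsets overlap within block")
            if m > 0:
                segs.append(self._make_segment(r, q, m))
                r += m
                q = q + m if self.strand == "+" else q - m
            r += ref_gap
            q = q + qry_gap if self.strand == "+" else q - qry_gap
        m = self.ref.end - r
        if m > 0:
            segs.append(self._make_segment(r, q, m))
            q = q + m if self.strand == "+" else q - m
        terminal = self.qry.end if self.strand == "+" else self.qry.start
        if q != terminal:
            raise ConsistencyError("block walk does not close on query interval")
        return segs

    def _make_segment(self, r: int, q: int, m: int) -> Segment:
        if self.strand == "+":
            return Segment(r, r + m, q, q + m)
        return Segment(r, r + m, q - m, q)

    # -- coverage -----------------------------------------------------------

    def ref_aligned_intervals(self, max_internal_gap: int = 10) -> list[Interval]:
        """Reference bp genuinely aligned to the query.

        Deleted reference spans longer than ``max_internal_gap`` are holes
        (the query has no counterpart there); smaller ones stay covered so
        that small indels do not fragment coverage.
        """
        holes = []
        r = self.ref.start
        for off, ref_gap, _ in self.gaps:
            pos = self.ref.start + off
            if ref_gap > max_internal_gap:
                holes.append(Interval(self.ref.chrom, pos, pos + ref_gap))
            r = pos + ref_gap
        return subtract([self.ref], holes)

    def qry_aligned_intervals(self, max_internal_gap: int = 10) -> list[Interval]:
        """Query bp genuinely aligned to the reference (cf. ref version)."""
        holes = []
        q = self.qry.start if self.strand == "+" else self.qry.end
        r = self.ref.start
        for off, ref_gap, qry_gap in self.gaps:
            m = (self.ref.start + off) - r
            r += m + ref_gap
            if self.strand == "+":
                q += m
                if qry_gap > max_internal_gap:
                    holes.append(Interval(self.qry.chrom, q, q + qry_gap))
                q += qry_gap
            else:
                q -= m
                if qry_gap > max_internal_gap:
                    holes.append(Interval(self.qry.chrom, q - qry_gap, q))
                q -= qry_gap
        return subtract([self.qry], holes)

    # -- slicing ------------------------------------------------------------

    def _from_segments(self, segs: list[Segment]) -> "AlignmentBlock | None":
        if not segs:
            return None
        gaps: list[tuple[int, int, int]] = []
        ref_start = segs[0].ref_start
        for prev, cur in zip(segs, segs[1:]):
            ref_gap = cur.ref_start - prev.ref_end
            if self.strand == "+":
                qry_gap = cur.qry_start - prev.qry_end
            else:
                qry_gap = prev.qry_start - cur.qry_end
            if ref_gap or qry_gap:
                gaps.append((prev.ref_end - ref_start, ref_gap, qry_gap))
        qs = min(s.qry_start for s in segs)
        qe = max(s.qry_end for s in segs)
        return AlignmentBlock(
            ref=Interval(self.ref.chrom, ref_start, segs[-1].ref_end),
            qry=Interval(self.qry.chrom, qs, qe),
            strand=self.strand,
            identity=self.identity,
            gaps=gaps,
        )

    def slice_by_ref(self, start: int, end: int) -> "AlignmentBlock | None":
        """Restrict the block to reference window [start, end).

        Identity is inherited from the parent block (an approximation; the
        per-window mismatch count is not retained).
        """
        segs = []
        for s in self.segments():
            lo, hi = max(s.ref_start, start), min(s.ref_end, end)
            if lo >= hi:
                continue
            if self.strand == "+":
                qs = s.qry_start + (lo - s.ref_start)
                segs.append(Segment(lo, hi, qs, qs + (hi - lo)))
            else:
                qe = s.qry_end - (lo - s.ref_start)
                segs.append(Segment(lo, hi, qe - (hi - lo), qe))
        return self._from_segments(segs)

    def slice_by_qry(self, start: int, end: int) -> "AlignmentBlock | None":
        """Restrict the block to query window [start, end)."""
        segs = []
        for s in self.segments():
            lo, hi = max(s.qry_start, start), min(s.qry_end, end)
            if lo >= hi:
                continue
            if self.strand == "+":
                rs = s.ref_start + (lo - s.qry_start)
                segs.append(Segment(rs, rs + (hi - lo), lo, hi))
            else:
                rs = s.ref_start + (s.qry_end - hi)
                segs.append(Segment(rs, rs + (hi - lo), lo, hi))
        return self._from_segments(segs)

    def split_at_large_gaps(self, threshold: int) -> list["AlignmentBlock"]:
        """Split into sub-blocks at internal gaps exceeding ``threshold`` bp.

        Used when serializing to coordinate files, whose rows cannot express
        internal gap structure: coverage semantics survive because large
        unaligned spans become inter-row space.
        """
        groups: list[list[Segment]] = [[]]
        segs = self.segments()
        if not segs:
            return []
        groups[0].append(segs[0])
        for prev, cur in zip(segs, segs[1:]):
            ref_gap = cur.ref_start - prev.ref_end
            qry_gap = (
                cur.qry_start - prev.qry_end
                if self.strand == "+"
                else prev.qry_start - cur.qry_end
            )
            if max(ref_gap, qry_gap) > threshold:
                groups.append([])
            groups[-1].append(cur)
        out = [self._from_segments(g) for g in groups]
        return [b for b in out if b is not None]


def sort_blocks(blocks: list[AlignmentBlock]) -> list[AlignmentBlock]:
    return sorted(blocks, key=lambda b: (b.ref.chrom, b.ref.start, b.ref.end))


def block_weight(block: AlignmentBlock) -> float:
    """Greedy selection weight: identity times aligned reference bp."""
    return block.identity * block.ref.length
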