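"""Genomic interval algebra.

All coordinates in tripan are 0-based, half-open ``[start, end)``. 1-based
inclusive coordinates exist only at file boundaries (see :mod:`tripan.io`),
which keeps every off-by-one conversion in one place.

Interval lists handled here live on a single chromosome namespace: every
operation groups by ``chrom`` internally, so callers may mix chromosomes
freely within one list.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import CoordinateError, UndefinedFractionError


@dataclass(frozen=True, order=True)
class Interval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0:
            raise CoordinateError(
                f"negative start {self.start} on {self.chrom}"
            )
        if self.start >= self.end:
            raise CoordinateError(
                f"empty or reversed interval [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_bp(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def _by_chrom(intervals: Iterable[Interval]) -> dict[str, list[Interval]]:
    groups: dict[str, list[Interval]] = defaultdict(list)
    for iv in intervals:
        groups[iv.chrom].append(iv)
    return groups


def merge_intervals(intervals: Sequence[Interval], max_gap: int = 0) -> list[Interval]:
    """Merge intervals whose separation is strictly less than ``max_gap``.

    A gap of exactly ``max_gap`` is *not* merged ("distance < 500 bp" reads as
    a strict inequality). Overlapping or bookended-with-negative-gap intervals
    always merge. With ``max_gap=0`` the total covered bp is unchanged.
    """
    if max_gap < 0:
        raise CoordinateError(f"max_gap must be >= 0, got {max_gap}")
    merged: list[Interval] = []
    for chrom in sorted(_by_chrom(intervals)):
        group = sorted(_by_chrom(intervals)[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = group[0].start, group[0].end
        for iv in group[1:]:
            if iv.start - cur_end < max_gap or iv.start < cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(Interval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(Interval(chrom, cur_start, cur_end))
    return merged


def total_bp(intervals: Iterable[Interval]) -> int:
    """Total covered bp of a *disjoint* interval list (merge first if unsure)."""
    return sum(iv.length for iv in merge_intervals(list(intervals), 0))


def intersect(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Intersection of two interval sets (each merged internally first)."""
    a_groups = _by_chrom(merge_intervals(list(a), 0))
    b_groups = _by_chrom(merge_intervals(list(b), 0))
    out: list[Interval] = []
    for chrom in sorted(set(a_groups) & set(b_groups)):
        ai, bi = a_groups[chrom], b_groups[chrom]
        i = j = 0
        while i < len(ai) and j < len(bi):
            lo = max(ai[i].start, bi[j].start)
            hi = min(ai[i].end, bi[j].end)
            if lo < hi:
                out.append(Interval(chrom, lo, hi))
            if ai[i].end < bi[j].end:
                i += 1
            else:
                j += 1
    return out


def subtract(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Set difference a \\ b as a disjoint interval list."""
    a_groups = _by_chrom(merge_intervals(list(a), 0))
    b_groups = _by_chrom(merge_intervals(list(b), 0))
    out: list[Interval] = []
    for chrom in sorted(a_groups):
        cuts = b_groups.get(chrom, [])
        for iv in a_groups[chrom]:
            pos = iv.start
            for cut in cuts:
                if cut.end <= pos or cut.start >= iv.end:
                    continue
                if cut.start > pos:
                    out.append(Interval(chrom, pos, cut.start))
                pos = max(pos, cut.end)
                if pos >= iv.end:
                    break
            if pos < iv.end:
                out.append(Interval(chrom, pos, iv.end))
    return out


def complement(
    intervals: Sequence[Interval], chrom_lengths: Mapping[str, int]
) -> list[Interval]:
    """Positions of each chromosome not covered by ``intervals``."""
    universe = [
        Interval(chrom, 0, length)
        for chrom, length in chrom_lengths.items()
        if length > 0
    ]
    return subtract(universe, intervals)


def covered_fraction(target: Sequence[Interval], cover: Sequence[Interval]) -> float:
    """Fraction of ``target`` bp that lies inside ``cover``.

    Raises :class:`UndefinedFractionError` for an empty target, since 0/0 has
    no meaningful gene-coverage interpretation.
    """
    denom = total_bp(target)
    if denom == 0:
        raise UndefinedFractionError("covered_fraction of an empty target")
    num = total_bp(intersect(target, cover))
    return num / denom
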