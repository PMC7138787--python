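"""Built-in pairwise whole-genome aligner.

Strategy: exact k-mer anchors (canonical, both strands), collapsed into
maximal exact runs, chained per (ref chromosome, qry chromosome, strand) by
a weighted longest-increasing-subsequence, with inter-anchor interstices
globally aligned (edlib) to recover mismatch columns and small indels. The
result is a list of :class:`~tripan.blocks.AlignmentBlock` with full gap
structure, suitable for coverage analysis and exact small-variant calling.

Two anchoring regimes:

* ``max_anchor_occ=1`` (default): k-mers unique in both genomes. Clean,
  repeat-free, and exactly reproducible by a brute-force hash join.
* ``max_anchor_occ>1`` ("sv" mode): k-mers occurring up to that many times
  per genome anchor every copy, so duplicated units produce the overlapping
  block signature that tandem expansion/contraction calling requires.

Chains shorter than ``min_chain_len`` anchored bp are dropped (the analog of
a minimum cluster size). Interstices larger than ``max_bridge`` are never
bridged and split chains into separate blocks.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .blocks import AlignmentBlock, block_weight, sort_blocks
from .config import DEFAULT_CONFIG, ThresholdConfig
from .errors import ParameterError
from .genome import GenomeSequence, revcomp
from .intervals import Interval, subtract

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass(frozen=True)
class Anchor:
    """An exact k-mer match between two genomes (equal-length intervals)."""

    ref: Interval
    qry: Interval
    strand: str


@dataclass
class _Run:
    """A maximal diagonal run of anchors (exact matched span)."""

    ref_chrom: str
    rs: int
    re: int
    qry_chrom: str
    qs: int
    qe: int
    strand: str

    @property
    def span(self) -> int:
        return self.re - self.rs


# -- k-mer tables -----------------------------------------------------------

def _global_codes(genome: GenomeSequence, k: int):
    """2-bit codes of all chromosomes concatenated with invalid spacers."""
    parts, starts, names = [], [], []
    spacer = np.full(k, 4, dtype=np.uint8)
    pos = 0
    for name, seq in genome.chromosomes:
        names.append(name)
        starts.append(pos)
        parts.append(_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)])
        parts.append(spacer)
        pos += len(seq) + k
    codes = np.concatenate(parts) if parts else np.zeros(0, dtype=np.uint8)
    return codes, np.asarray(starts, dtype=np.int64), names


def _kmer_arrays(codes: np.ndarray, k: int):
    """(canonical kmer, forward-is-canonical, start position) for valid windows."""
    n = len(codes) - k + 1
    if n <= 0:
        empty = np.zeros(0, dtype=np.int64)
        return empty, np.zeros(0, dtype=bool), empty
    vals = codes.astype(np.int64)
    fwd = np.zeros(n, dtype=np.int64)
    invalid = np.zeros(n, dtype=bool)
    for j in range(k):
        window = vals[j : j + n]
        fwd = fwd * 4 + window
        invalid |= window == 4
    rc = np.zeros(n, dtype=np.int64)
    for j in range(k - 1, -1, -1):
        rc = rc * 4 + (3 - vals[j : j + n])
    valid = ~invalid
    canon = np.minimum(fwd, rc)
    orient = fwd <= rc
    pos = np.arange(n, dtype=np.int64)
    return canon[valid], orient[valid], pos[valid]


def _match_kmers(ref_tab, qry_tab, max_occ: int):
    """Join canonical k-mer tables; returns (rpos, qpos, plus_strand)."""
    canon_r, orient_r, pos_r = ref_tab
    canon_q, orient_q, pos_q = qry_tab
    if max_occ == 1:
        uniq_r, first_r, cnt_r = np.unique(
            canon_r, return_index=True, return_counts=True
        )
        uniq_q, first_q, cnt_q = np.unique(
            canon_q, return_index=True, return_counts=True
        )
        keep_r, keep_q = cnt_r == 1, cnt_q == 1
        _, ir, iq = np.intersect1d(
            uniq_r[keep_r], uniq_q[keep_q], assume_unique=True, return_indices=True
        )
        idx_r = first_r[keep_r][ir]
        idx_q = first_q[keep_q][iq]
        rpos, qpos = pos_r[idx_r], pos_q[idx_q]
        plus = orient_r[idx_r] == orient_q[idx_q]
        return rpos, qpos, plus
    # multi-occurrence join via pandas (many-to-many)
    uniq_r, inv_r, cnt_r = np.unique(canon_r, return_inverse=True, return_counts=True)
    uniq_q, inv_q, cnt_q = np.unique(canon_q, return_inverse=True, return_counts=True)
    mask_r = cnt_r[inv_r] <= max_occ
    mask_q = cnt_q[inv_q] <= max_occ
    df_r = pd.DataFrame(
        {"k": canon_r[mask_r], "rp": pos_r[mask_r], "ro": orient_r[mask_r]}
    )
    df_q = pd.DataFrame(
        {"k": canon_q[mask_q], "qp": pos_q[mask_q], "qo": orient_q[mask_q]}
    )
    joined = df_r.merge(df_q, on="k", how="inner")
    return (
        joined["rp"].to_numpy(),
        joined["qp"].to_numpy(),
        (joined["ro"] == joined["qo"]).to_numpy(),
    )


def _anchor_arrays(ref: GenomeSequence, qry: GenomeSequence, k: int, max_occ: int):
    ref_codes, ref_starts, ref_names = _global_codes(ref, k)
    qry_codes, qry_starts, qry_names = _global_codes(qry, k)
    rpos, qpos, plus = _match_kmers(
        _kmer_arrays(ref_codes, k), _kmer_arrays(qry_codes, k), max_occ
    )
    return (rpos, qpos, plus), (ref_starts, ref_names), (qry_starts, qry_names)


def _locate(pos: np.ndarray, starts: np.ndarray):
    idx = np.searchsorted(starts, pos, side="right") - 1
    return idx, pos - starts[idx]


# -- runs -------------------------------------------------------------------

def _collapse_runs(anchors, ref_loc, qry_loc, k: int) -> list[_Run]:
    rpos, qpos, plus = anchors
    ref_starts, ref_names = ref_loc
    qry_starts, qry_names = qry_loc
    if len(rpos) == 0:
        return []
    r_chrom, r_local = _locate(rpos, ref_starts)
    q_chrom, q_local = _locate(qpos, qry_starts)
    runs: list[_Run] = []
    for strand_plus in (True, False):
        mask = plus == strand_plus
        if not mask.any():
            continue
        rc, rl = r_chrom[mask], r_local[mask]
        qc, ql = q_chrom[mask], q_local[mask]
        diag = ql - rl if strand_plus else ql + rl
        order = np.lexsort((rl, diag, qc, rc))
        rc, rl, qc, ql, diag = (a[order] for a in (rc, rl, qc, ql, diag))
        new = np.ones(len(rl), dtype=bool)
        new[1:] = (
            (diag[1:] != diag[:-1])
            | (rl[1:] != rl[:-1] + 1)
            | (rc[1:] != rc[:-1])
            | (qc[1:] != qc[:-1])
        )
        starts = np.flatnonzero(new)
        ends = np.r_[starts[1:], len(rl)] - 1
        for s, e in zip(starts, ends):
            if strand_plus:
                runs.append(
                    _Run(ref_names[rc[s]], int(rl[s]), int(rl[e]) + k,
                         qry_names[qc[s]], int(ql[s]), int(ql[e]) + k, "+")
                )
            else:
                runs.append(
                    _Run(ref_names[rc[s]], int(rl[s]), int(rl[e]) + k,
                         qry_names[qc[s]], int(ql[e]), int(ql[s]) + k, "-")
                )
    return runs


# -- chaining ---------------------------------------------------------------

_LOOKBACK = 64
_GAP_PENALTY = 0.01


def _chain_group(runs: list[_Run], cfg: ThresholdConfig) -> list[list[_Run]]:
    """Iteratively extract best collinear chains from one (chrom, chrom,
    strand) group of runs; runs are consumed by at most one chain.

    Adjacent runs may overlap by up to k-1 bp (k-mer span extension past the
    last divergent column); such overlaps are chainable and trimmed away
    when blocks are built.
    """
    chains: list[list[_Run]] = []
    slack = cfg.anchor_k - 1
    remaining = sorted(runs, key=lambda r: (r.rs, r.re))
    while remaining:
        n = len(remaining)
        score = [float(r.span) for r in remaining]
        back = [-1] * n
        for j in range(n):
            rj = remaining[j]
            lo = max(0, j - _LOOKBACK)
            for i in range(lo, j):
                ri = remaining[i]
                if rj.re <= ri.re:
                    continue  # no reference progress
                dr = rj.rs - ri.re
                if dr < -slack or dr > cfg.max_bridge:
                    continue
                if rj.strand == "+":
                    if rj.qe <= ri.qe:
                        continue
                    dq = rj.qs - ri.qe
                else:
                    if rj.qs >= ri.qs:
                        continue
                    dq = ri.qs - rj.qe
                if dq < -slack or dq > cfg.max_bridge:
                    continue
                cand = score[i] + rj.span - _GAP_PENALTY * (abs(dr) + abs(dq))
                if cand > score[j]:
                    score[j] = cand
                    back[j] = i
        best_j = int(np.argmax(score))
        if score[best_j] < cfg.min_chain_len:
            break
        chain_idx = []
        j = best_j
        while j != -1:
            chain_idx.append(j)
            j = back[j]
        chain_idx.reverse()
        chain = [remaining[j] for j in chain_idx]
        if sum(r.span for r in chain) >= cfg.min_chain_len:
            chains.append(chain)
        used = set(chain_idx)
        remaining = [r for j, r in enumerate(remaining) if j not in used]
        if len(chains) > 5000:  # safety valve for pathological repeat soup
            break
    return chains


# -- block construction -----------------------------------------------------

def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


class _BlockBuilder:
    def __init__(self, ref_chrom: str, qry_chrom: str, strand: str,
                 rs: int, q_anchor: int):
        # q_anchor: qry start ('+') or qry end ('-') of the walk
        self.ref_chrom, self.qry_chrom, self.strand = ref_chrom, qry_chrom, strand
        self.r0, self.q0 = rs, q_anchor
        self.ops: list[tuple[str, int]] = []  # ('M'|'D'|'I', length)
        self.matches = 0
        self.mismatches = 0
        self.gap_cols = 0

    def add(self, op: str, length: int, matched: int = 0):
        if length <= 0:
            return
        if self.ops and self.ops[-1][0] == op == "M":
            self.ops[-1] = ("M", self.ops[-1][1] + length)
        else:
            self.ops.append((op, length))
        if op == "M":
            self.matches += matched
            self.mismatches += length - matched
        else:
            self.gap_cols += length

    def build(self) -> AlignmentBlock | None:
        ref_len = sum(n for op, n in self.ops if op in "MD")
        qry_len = sum(n for op, n in self.ops if op in "MI")
        if ref_len == 0 or qry_len == 0:
            return None
        gaps = []
        r_off = 0
        pending = None  # coalesce adjacent D/I at one site into one record
        for op, n in self.ops:
            if op == "M":
                if pending:
                    gaps.append(pending)
                    pending = None
                r_off += n
            elif op == "D":
                if pending:
                    pending = (pending[0], pending[1] + n, pending[2])
                else:
                    pending = (r_off, n, 0)
                r_off += n
            else:  # I
                if pending:
                    pending = (pending[0], pending[1], pending[2] + n)
                else:
                    pending = (r_off, 0, n)
        if pending:
            gaps.append(pending)
        columns = self.matches + self.mismatches + self.gap_cols
        identity = self.matches / columns if columns else 0.0
        ref = Interval(self.ref_chrom, self.r0, self.r0 + ref_len)
        if self.strand == "+":
            qry = Interval(self.qry_chrom, self.q0, self.q0 + qry_len)
        else:
            qry = Interval(self.qry_chrom, self.q0 - qry_len, self.q0)
        return AlignmentBlock(ref=ref, qry=qry, strand=self.strand,
                              identity=identity, gaps=gaps)


def _interstice_bridgeable(dr: int, dq: int, cfg: ThresholdConfig,
                           mode: str) -> bool:
    if max(dr, dq) > cfg.max_bridge:
        return False
    if mode == "sv":
        # keep structural differences between blocks so the six-category
        # classifier sees them as inter-block signals
        return abs(dq - dr) < cfg.large_variant_min
    return True


_JUNK_IDENTITY = 0.75   # below this an interstice is unrelated sequence
_JUNK_MIN_LEN = 30      # edlib-path interstices longer than this can be junked
_COLUMN_MIN_LEN = 4     # columnwise stretches longer than this can be junked


def _matched(a: str, b: str) -> int:
    return sum(x == y for x, y in zip(a, b))


def _emit_columns(ops: list, a: str, b: str):
    """Equal-length columnwise comparison; unrelated stretches become a
    double-sided gap rather than a wall of mismatch columns."""
    m = _matched(a, b)
    frac = m / len(a)
    junk = (len(a) > _JUNK_MIN_LEN and frac < _JUNK_IDENTITY) or (
        len(a) > _COLUMN_MIN_LEN and frac < 0.5
    )
    if junk:
        ops.append(("D", len(a), 0))
        ops.append(("I", len(b), 0))
    else:
        ops.append(("M", len(a), m))


def _align_interstice(builder: _BlockBuilder, ref_seq: str, qry_seq: str):
    """Fill the gap between two runs; qry_seq is already strand-oriented.

    Policy: equal-length interstices are compared column by column (exact
    SNP placement); strongly unbalanced ones are anchored at their common
    ends so the single dominant indel keeps an exact breakpoint; the rest
    go through global alignment. In every path, low-identity stretches are
    recorded as unaligned (deleted + inserted) sequence — forcing unrelated
    sequence into an alignment would fake coverage where there is none.
    """
    dr, dq = len(ref_seq), len(qry_seq)
    ops: list[tuple[str, int, int]] = []
    if dr == 0 and dq == 0:
        return
    elif dr == 0:
        ops.append(("I", dq, 0))
    elif dq == 0:
        ops.append(("D", dr, 0))
    elif dr == dq:
        _emit_columns(ops, ref_seq, qry_seq)
    elif abs(dr - dq) >= 20:
        # a dominant indel: global aligners shred these (threading the
        # short side through the long side to buy back mismatches), so
        # anchor the ends greedily and leave one clean gap
        short, long_ = (ref_seq, qry_seq) if dr <= dq else (qry_seq, ref_seq)

        def _extend(get_a, get_b, limit: int) -> int:
            # greedy extension tolerating isolated mismatches (an isolated
            # substitution should not stop the breakpoint short)
            i = 0
            while i < limit:
                if get_a(i) == get_b(i):
                    i += 1
                elif (i + 2 < limit and get_a(i + 1) == get_b(i + 1)
                      and get_a(i + 2) == get_b(i + 2)):
                    i += 1
                else:
                    break
            return i

        p = _extend(lambda i: short[i], lambda i: long_[i], len(short))
        s = _extend(lambda i: short[len(short) - 1 - i],
                    lambda i: long_[len(long_) - 1 - i], len(short) - p)
        mid_short = len(short) - p - s
        mid_long = len(long_) - p - s
        sub_ops: list[tuple[str, int, int]] = []
        if p:
            sub_ops.append(("M", p, _matched(short[:p], long_[:p])))
        if mid_short:
            _emit_columns(sub_ops, short[p : p + mid_short],
                          long_[p : p + mid_short])
        sub_ops.append(("D" if dr > dq else "I", mid_long - mid_short, 0))
        if s:
            sub_ops.append(("M", s, _matched(short[len(short) - s:],
                                             long_[len(long_) - s:])))
        ops.extend(sub_ops)
    else:
        result = edlib.align(qry_seq, ref_seq, mode="NW", task="path")
        # Unrelated sequence: the edit distance in excess of the pure
        # length difference approaches ~0.5 per aligned base, while truly
        # homologous interstices stay near the local divergence rate.
        excess = result["editDistance"] - abs(dr - dq)
        if min(dr, dq) > _JUNK_MIN_LEN and excess / min(dr, dq) > 0.3:
            ops = [("D", dr, 0), ("I", dq, 0)]
        else:
            ri = qi = 0
            for n, op in _cigar_ops(result["cigar"]):
                if op in ("=", "X", "M"):
                    ops.append(("M", n, _matched(ref_seq[ri : ri + n],
                                                 qry_seq[qi : qi + n])))
                    ri += n
                    qi += n
                elif op == "I":  # query-only bases
                    ops.append(("I", n, 0))
                    qi += n
                elif op == "D":  # target(ref)-only bases
                    ops.append(("D", n, 0))
                    ri += n
    for op, n, m in ops:
        builder.add(op, n, m)


def _chain_to_blocks(chain: list[_Run], ref: GenomeSequence, qry: GenomeSequence,
                     cfg: ThresholdConfig, mode: str) -> list[AlignmentBlock]:
    blocks: list[AlignmentBlock] = []
    first = chain[0]
    strand = first.strand
    ref_seq = ref.seq(first.ref_chrom)
    qry_seq = qry.seq(first.qry_chrom)

    def orient(qlo: int, qhi: int) -> str:
        s = qry_seq[qlo:qhi]
        return s if strand == "+" else revcomp(s)

    builder = _BlockBuilder(first.ref_chrom, first.qry_chrom, strand,
                            first.rs, first.qs if strand == "+" else first.qe)
    builder.add("M", first.span, first.span)
    prev = first
    for run in chain[1:]:
        # trim away k-mer-extension overlap with the previous run
        if strand == "+":
            trim = max(prev.re - run.rs, prev.qe - run.qs, 0)
        else:
            trim = max(prev.re - run.rs, run.qe - prev.qs, 0)
        if trim:
            if trim >= run.span:
                continue
            if strand == "+":
                run = _Run(run.ref_chrom, run.rs + trim, run.re,
                           run.qry_chrom, run.qs + trim, run.qe, strand)
            else:
                run = _Run(run.ref_chrom, run.rs + trim, run.re,
                           run.qry_chrom, run.qs, run.qe - trim, strand)
        dr = run.rs - prev.re
        dq = run.qs - prev.qe if strand == "+" else prev.qs - run.qe
        if _interstice_bridgeable(dr, dq, cfg, mode):
            ref_gap = ref_seq[prev.re : run.rs]
            if strand == "+":
                qry_gap = orient(prev.qe, run.qs)
            else:
                qry_gap = orient(run.qe, prev.qs)
            _align_interstice(builder, ref_gap, qry_gap)
        else:
            blk = builder.build()
            if blk is not None:
                blocks.append(blk)
            builder = _BlockBuilder(run.ref_chrom, run.qry_chrom, strand,
                                    run.rs, run.qs if strand == "+" else run.qe)
        builder.add("M", run.span, run.span)
        prev = run
    blk = builder.build()
    if blk is not None:
        blocks.append(blk)
    return blocks


# -- public API -------------------------------------------------------------

def _validate_k(k: int):
    if k % 2 == 0 or not 11 <= k <= 31:
        raise ParameterError(f"k must be odd and within [11, 31], got {k}")


def find_anchors(ref: GenomeSequence, qry: GenomeSequence, k: int,
                 max_occ: int = 1) -> list[Anchor]:
    """All exact k-mer matches whose canonical k-mer occurs at most
    ``max_occ`` times in each genome (default: unique in both).

    Both strands are searched; reverse-strand anchors carry ascending query
    coordinates and ``strand='-'``.
    """
    _validate_k(k)
    anchors_arr, ref_loc, qry_loc = _anchor_arrays(ref, qry, k, max_occ)
    rpos, qpos, plus = anchors_arr
    ref_starts, ref_names = ref_loc
    qry_starts, qry_names = qry_loc
    r_chrom, r_local = _locate(rpos, ref_starts)
    q_chrom, q_local = _locate(qpos, qry_starts)
    out = []
    for i in range(len(rpos)):
        out.append(
            Anchor(
                ref=Interval(ref_names[r_chrom[i]], int(r_local[i]),
                             int(r_local[i]) + k),
                qry=Interval(qry_names[q_chrom[i]], int(q_local[i]),
                             int(q_local[i]) + k),
                strand="+" if plus[i] else "-",
            )
        )
    return sorted(out, key=lambda a: (a.ref.chrom, a.ref.start, a.qry.chrom,
                                      a.qry.start))


def chain_and_extend(anchors: list[Anchor], ref: GenomeSequence,
                     qry: GenomeSequence, config: ThresholdConfig = DEFAULT_CONFIG,
                     mode: str = "collinear") -> list[AlignmentBlock]:
    """Chain anchors into alignment blocks with populated gap structure."""
    k = anchors[0].ref.length if anchors else config.anchor_k
    runs_by_group: dict[tuple, list[_Run]] = defaultdict(list)
    # rebuild maximal runs from individual anchors
    by_key = defaultdict(list)
    for a in anchors:
        diag = a.qry.start - a.ref.start if a.strand == "+" else a.qry.start + a.ref.start
        by_key[(a.ref.chrom, a.qry.chrom, a.strand, diag)].append(a)
    for (rchrom, qchrom, strand, _diag), group in by_key.items():
        group.sort(key=lambda a: a.ref.start)
        cur = [group[0]]
        for a in group[1:]:
            if a.ref.start == cur[-1].ref.start + 1:
                cur.append(a)
            else:
                runs_by_group[(rchrom, qchrom, strand)].append(
                    _run_from_anchors(cur, k)
                )
                cur = [a]
        runs_by_group[(rchrom, qchrom, strand)].append(_run_from_anchors(cur, k))
    blocks: list[AlignmentBlock] = []
    for group_runs in runs_by_group.values():
        for chain in _chain_group(group_runs, config):
            blocks.extend(_chain_to_blocks(chain, ref, qry, config, mode))
    return sort_blocks(blocks)


def _run_from_anchors(anchors: list[Anchor], k: int) -> _Run:
    first, last = anchors[0], anchors[-1]
    qs = min(first.qry.start, last.qry.start)
    qe = max(first.qry.end, last.qry.end)
    return _Run(first.ref.chrom, first.ref.start, last.ref.end,
                first.qry.chrom, qs, qe, first.strand)


def align_genomes(ref: GenomeSequence, qry: GenomeSequence,
                  config: ThresholdConfig = DEFAULT_CONFIG,
                  mode: str = "collinear") -> list[AlignmentBlock]:
    """Full anchoring + chaining + extension for one genome pair.

    ``mode='collinear'`` (pan-genome / small variants): unique anchors,
    liberal interstice bridging. ``mode='sv'``: multi-occurrence anchors,
    structural differences left between blocks for the SV classifier.
    """
    if mode not in ("collinear", "sv"):
        raise ParameterError(f"unknown alignment mode {mode!r}")
    cfg = config.sv_mode() if mode == "sv" and config.max_anchor_occ == 1 else config
    _validate_k(cfg.anchor_k)
    anchors_arr, ref_loc, qry_loc = _anchor_arrays(
        ref, qry, cfg.anchor_k, cfg.max_anchor_occ
    )
    runs = _collapse_runs(anchors_arr, ref_loc, qry_loc, cfg.anchor_k)
    groups: dict[tuple, list[_Run]] = defaultdict(list)
    for run in runs:
        groups[(run.ref_chrom, run.qry_chrom, run.strand)].append(run)
    blocks: list[AlignmentBlock] = []
    for group_runs in groups.values():
        for chain in _chain_group(group_runs, cfg):
            blocks.extend(_chain_to_blocks(chain, ref, qry, cfg, mode))
    return dedup_contained(blocks)


def filter_one_to_one(blocks: list[AlignmentBlock]) -> list[AlignmentBlock]:
    """Greedy one-to-one filtering by identity-weighted aligned bp.

    Blocks are admitted in decreasing weight; a candidate overlapping already
    accepted coverage is trimmed to its largest uncovered piece on each
    genome. The returned set covers no reference or query position twice.
    """
    ref_cov: dict[str, IntervalTree] = defaultdict(IntervalTree)
    qry_cov: dict[str, IntervalTree] = defaultdict(IntervalTree)
    kept: list[AlignmentBlock] = []

    def largest_uncovered(iv: Interval, cov: dict[str, IntervalTree]):
        hits = [Interval(iv.chrom, max(h.begin, iv.start), min(h.end, iv.end))
                for h in cov[iv.chrom].overlap(iv.start, iv.end)]
        free = subtract([iv], hits)
        if not free:
            return None
        return max(free, key=lambda f: f.length)

    for block in sorted(blocks, key=block_weight, reverse=True):
        piece = block
        free_ref = largest_uncovered(piece.ref, ref_cov)
        if free_ref is None:
            continue
        if free_ref != piece.ref:
            piece = piece.slice_by_ref(free_ref.start, free_ref.end)
            if piece is None:
                continue
        free_qry = largest_uncovered(piece.qry, qry_cov)
        if free_qry is None:
            continue
        if free_qry != piece.qry:
            piece = piece.slice_by_qry(free_qry.start, free_qry.end)
            if piece is None:
                continue
            # query slicing shrinks the reference side; re-check it
            free_ref = largest_uncovered(piece.ref, ref_cov)
            if free_ref is None:
                continue
            if free_ref != piece.ref:
                piece = piece.slice_by_ref(free_ref.start, free_ref.end)
                if piece is None:
                    continue
        kept.append(piece)
        ref_cov[piece.ref.chrom].addi(piece.ref.start, piece.ref.end)
        qry_cov[piece.qry.chrom].addi(piece.qry.start, piece.qry.end)
    return sort_blocks(kept)


def dedup_contained(blocks: list[AlignmentBlock]) -> list[AlignmentBlock]:
    """Drop blocks nested inside another block on both genomes.

    The lenient alternative to strict one-to-one filtering used before
    structural-variant classification, where partial overlaps between blocks
    are themselves the signal (tandem expansions/contractions).
    """
    keep = []
    ordered = sorted(blocks, key=lambda b: -b.ref.length)
    for b in ordered:
        nested = any(
            k.ref.chrom == b.ref.chrom and k.qry.chrom == b.qry.chrom
            and k.ref.start <= b.ref.start and b.ref.end <= k.ref.end
            and k.qry.start <= b.qry.start and b.qry.end <= k.qry.end
            for k in keep
        )
        if not nested:
            keep.append(b)
    return sort_blocks(keep)
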