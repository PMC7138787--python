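"""Anchoring, chaining, extension and one-to-one filtering."""

from itertools import combinations

import numpy as np
import pytest

from conftest import random_genome
from tripan.align import (
    Anchor, align_genomes, chain_and_extend, dedup_contained, find_anchors,
    filter_one_to_one,
)
from tripan.blocks import AlignmentBlock, block_weight
from tripan.config import ThresholdConfig
from tripan.errors import ParameterError
from tripan.genome import GenomeSequence, revcomp
from tripan.intervals import Interval


def brute_force_anchors(ref: GenomeSequence, qry: GenomeSequence, k: int):
    """Independent hash-join oracle over canonical k-mers unique in both."""
    def kmer_table(genome):
        table = {}
        for chrom, seq in genome.chromosomes:
            for i in range(len(seq) - k + 1):
                mer = seq[i : i + k]
                if "N" in mer:
                    continue
                canon = min(mer, revcomp(mer))
                table.setdefault(canon, []).append(
                    (chrom, i, mer <= revcomp(mer))
                )
        return table
    tr, tq = kmer_table(ref), kmer_table(qry)
    out = set()
    for canon, rhits in tr.items():
        qhits = tq.get(canon)
        if qhits is None or len(rhits) != 1 or len(qhits) != 1:
            continue
        (rc, rp, rfwd), (qc, qp, qfwd) = rhits[0], qhits[0]
        strand = "+" if rfwd == qfwd else "-"
        out.add((rc, rp, qc, qp, strand))
    return out


class TestFindAnchors:
    def test_k_validation(self, rng):
        g = random_genome(rng, 200)
        for bad_k in (10, 9, 33, 22):
            with pytest.raises(ParameterError):
                find_anchors(g, g, bad_k)

    def test_identical_sequences_tile(self, rng):
        g = random_genome(rng, 2_000)
        anchors = find_anchors(g, g, 21)
        starts = {a.ref.start for a in anchors}
        # every unique k-mer position must anchor to itself
        assert starts == {a.qry.start for a in anchors}
        assert len(starts) > 1900
        assert all(a.strand == "+" for a in anchors)

    def test_reverse_complement_all_minus(self, rng):
        g = random_genome(rng, 2_000)
        rc = GenomeSequence("rc", [("chr1", revcomp(g.seq("chr1")))])
        anchors = find_anchors(g, rc, 21)
        assert anchors and all(a.strand == "-" for a in anchors)

    def test_hash_join_oracle(self, rng):
        ref = random_genome(rng, 3_000, genome_id="r")
        # query: a shuffled splice of the reference plus novel sequence
        seq = ref.seq("chr1")
        qry_seq = seq[1500:] + "".join(
            "ACGT"[i] for i in rng.integers(0, 4, 500)
        ) + revcomp(seq[:1000])
        qry = GenomeSequence("q", [("chr1", qry_seq)])
        got = {
            (a.ref.chrom, a.ref.start, a.qry.chrom, a.qry.start, a.strand)
            for a in find_anchors(ref, qry, 21)
        }
        assert got == brute_force_anchors(ref, qry, 21)


class TestChainAndExtend:
    def test_identical_single_perfect_block(self, rng):
        g = random_genome(rng, 5_000)
        anchors = find_anchors(g, g, 21)
        [block] = chain_and_extend(anchors, g, g)
        assert block.identity == 1.0 and block.gaps == []
        assert block.ref == Interval("chr1", 0, 5_000)

    def test_insertion_bridged_into_gap(self, rng):
        g = random_genome(rng, 6_000)
        seq = g.seq("chr1")
        ins = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        qry = GenomeSequence("q", [("chr1", seq[:3000] + ins + seq[3000:])])
        blocks = align_genomes(g, qry)
        assert len(blocks) == 1
        [gap] = blocks[0].gaps
        assert gap == (3000, 0, 500)

    def test_snp_identity_within_binomial_bound(self, rng):
        n = 50_000
        g = random_genome(rng, n)
        seq = list(g.seq("chr1"))
        sites = rng.choice(n, size=n // 100, replace=False)
        for s in sites:
            seq[s] = "ACGT"[("ACGT".index(seq[s]) + 2) % 4]
        qry = GenomeSequence("q", [("chr1", "".join(seq))])
        blocks = align_genomes(g, qry)
        matched = sum(b.identity * b.ref.length for b in blocks)
        total = sum(b.ref.length for b in blocks)
        p = 0.99
        sigma = np.sqrt(p * (1 - p) / total)
        assert abs(matched / total - p) < 4 * sigma


class TestOneToOne:
    def _block(self, rs, re, qs, qe, identity):
        return AlignmentBlock(ref=Interval("c", rs, re),
                              qry=Interval("c", qs, qe), strand="+",
                              identity=identity, gaps=[])

    def test_non_overlapping_unchanged(self):
        blocks = [self._block(0, 100, 0, 100, 0.99),
                  self._block(200, 300, 200, 300, 0.95)]
        assert filter_one_to_one(blocks) == blocks

    def test_higher_identity_wins_duplicate_ref(self):
        lo = self._block(0, 100, 500, 600, 0.90)
        hi = self._block(0, 100, 0, 100, 0.99)
        kept = filter_one_to_one([lo, hi])
        assert len(kept) == 1 and kept[0].identity == 0.99

    def test_greedy_near_optimal_on_random_instances(self, rng):
        def score(blocks):
            return sum(block_weight(b) for b in blocks)

        def compatible(blocks):
            for a, b in combinations(blocks, 2):
                if a.ref.overlaps(b.ref) or a.qry.overlaps(b.qry):
                    return False
            return True

        for trial in range(5):
            blocks = []
            for _ in range(14):
                rs = int(rng.integers(0, 900))
                ln = int(rng.integers(50, 400))
                qs = int(rng.integers(0, 900))
                blocks.append(self._block(rs, rs + ln, qs, qs + ln,
                                          float(rng.uniform(0.85, 1.0))))
            best = max(
                (score(sub) for r in range(len(blocks) + 1)
                 for sub in combinations(blocks, r) if compatible(sub)),
                default=0.0,
            )
            got = score(filter_one_to_one(blocks))
            # trimming lets greedy keep partial credit, so it may exceed the
            # untrimmed optimum; it must never fall more than 5% below it
            assert got >= 0.95 * best

    def test_output_is_disjoint_on_both_genomes(self, rng):
        blocks = []
        for _ in range(30):
            rs = int(rng.integers(0, 2_000))
            ln = int(rng.integers(50, 500))
            qs = int(rng.integers(0, 2_000))
            blocks.append(self._block(rs, rs + ln, qs, qs + ln,
                                      float(rng.uniform(0.9, 1.0))))
        kept = filter_one_to_one(blocks)
        for a, b in combinations(kept, 2):
            assert not a.ref.overlaps(b.ref)
            assert not a.qry.overlaps(b.qry)


class TestWholeGenomeProperties:
    def test_self_alignment_near_full_coverage(self, rng):
        g = random_genome(rng, 30_000)
        blocks = align_genomes(g, g)
        covered = sum(
            iv.length for b in blocks for iv in b.ref_aligned_intervals(10)
        )
        assert covered >= 0.99 * g.total_length
        assert all(b.identity == 1.0 for b in blocks)

    def test_coverage_symmetry(self):
        from tripan.simulate import EvolutionParams, evolve, simulate_ancestor
        anc = simulate_ancestor(60_000, seed=3)
        derived, _ = evolve(anc, EvolutionParams(pav_count=4,
                                                 pav_len=(500, 1500), seed=4))
        ab = filter_one_to_one(align_genomes(anc, derived))
        ba = filter_one_to_one(align_genomes(derived, anc))
        cov_ab = sum(iv.length for b in ab for iv in b.ref_aligned_intervals(10))
        cov_ba = sum(iv.length for b in ba for iv in b.qry_aligned_intervals(10))
        assert abs(cov_ab - cov_ba) / cov_ab < 0.01

    def test_block_invariants_hold(self, sv_free_pair):
        blocks = align_genomes(sv_free_pair["ref"], sv_free_pair["qry"])
        for b in blocks:
            segs = b.segments()  # walk closes on the query interval
            assert segs
            assert 0.0 <= b.identity <= 1.0

    def test_dedup_contained_removes_nested(self):
        outer = AlignmentBlock(ref=Interval("c", 0, 1000),
                               qry=Interval("c", 0, 1000), strand="+",
                               identity=0.99, gaps=[])
        inner = AlignmentBlock(ref=Interval("c", 100, 200),
                               qry=Interval("c", 100, 200), strand="+",
                               identity=1.0, gaps=[])
        assert dedup_contained([outer, inner]) == [outer]
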