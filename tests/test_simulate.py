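"""Simulator: determinism, truth replay, composition bounds, gene ORFs."""

import numpy as np
import pytest

from tripan.errors import ParameterError, PlacementError
from tripan.genome import translate
from tripan.intervals import Interval
from tripan.simulate import (
    EvolutionParams, evolve, lift_genes, plant_genes, simulate_ancestor,
    simulate_depth,
)


class TestAncestor:
    def test_zero_length(self):
        assert simulate_ancestor(0).total_length == 0

    def test_deterministic(self):
        a = simulate_ancestor(50_000, gc=0.43, seed=5)
        b = simulate_ancestor(50_000, gc=0.43, seed=5)
        assert a.chromosomes == b.chromosomes

    def test_gc_within_binomial_bound(self):
        n = 1_000_000
        g = simulate_ancestor(n, gc=0.43, seed=9)
        sigma = np.sqrt(0.43 * 0.57 / n)
        assert abs(g.gc_fraction() - 0.43) < 4 * sigma

    def test_bad_params(self):
        with pytest.raises(ParameterError):
            simulate_ancestor(-1)
        with pytest.raises(ParameterError):
            simulate_ancestor(10, gc=1.5)


class TestPlantGenes:
    def test_zero_genes(self, ancestor_100k):
        genome, genes = plant_genes(ancestor_100k, 0)
        assert genes == [] and genome is ancestor_100k

    def test_orfs_are_clean(self, genic_ancestor):
        genome, genes = genic_ancestor
        assert len(genes) == 20
        for gene in genes:
            cds = gene.coding_sequence(genome)
            assert len(cds) % 3 == 0
            protein = translate(cds)
            assert protein[0] == "M"
            assert protein.endswith("*")
            assert "*" not in protein[:-1]

    def test_deterministic(self, ancestor_100k):
        _, g1 = plant_genes(ancestor_100k, 10, seed=3)
        _, g2 = plant_genes(ancestor_100k, 10, seed=3)
        assert g1 == g2

    def test_genes_do_not_overlap(self, genic_ancestor):
        _, genes = genic_ancestor
        spans = sorted((g.chrom, g.span.start, g.span.end) for g in genes)
        for (c1, _, e1), (c2, s2, _) in zip(spans, spans[1:]):
            assert c1 != c2 or s2 >= e1

    def test_insufficient_space(self):
        tiny = simulate_ancestor(500, seed=1)
        with pytest.raises(PlacementError):
            plant_genes(tiny, 10, cds_len_range=(300, 450))


class TestEvolve:
    def test_zero_rates_identity(self, ancestor_100k):
        params = EvolutionParams(snp_rate=0.0, indel_rate=0.0, pav_count=0,
                                 cnv_count=0, seed=1)
        derived, truth = evolve(ancestor_100k, params)
        assert derived.chromosomes == ancestor_100k.chromosomes
        assert truth.events == []

    def test_replay_reproduces_derived(self, sv_free_pair):
        replayed = sv_free_pair["truth"].replay(sv_free_pair["ref"])
        assert replayed.chromosomes == sv_free_pair["qry"].chromosomes

    def test_snp_count_binomial_bound(self):
        anc = simulate_ancestor(1_000_000, seed=21)
        params = EvolutionParams(snp_rate=0.005, indel_rate=0.0, pav_count=0,
                                 seed=22)
        _, truth = evolve(anc, params)
        n, p = 1_000_000, 0.005
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(len(truth.by_type("snp")) - n * p) < 4 * sigma

    def test_length_bookkeeping_with_gains(self, ancestor_100k):
        params = EvolutionParams(snp_rate=0.0, indel_rate=0.0, pav_count=10,
                                 pav_len=(1000, 1000), pav_gain_frac=1.0,
                                 seed=5)
        derived, truth = evolve(ancestor_100k, params)
        assert derived.total_length == ancestor_100k.total_length + 10_000
        assert len(truth.by_type("pav_gain")) == 10

    def test_events_do_not_overlap(self, sv_free_pair):
        events = sorted(sv_free_pair["truth"].events,
                        key=lambda e: (e.chrom, e.donor_start))
        for a, b in zip(events, events[1:]):
            assert a.chrom != b.chrom or b.donor_start >= a.donor_end

    def test_purifying_mode_cds_indels_multiple_of_three(self, genic_ancestor):
        genome, genes = genic_ancestor
        params = EvolutionParams(snp_rate=0.0, indel_rate=2e-3, pav_count=0,
                                 purifying=True, seed=31)
        _, truth = evolve(genome, params, genes=genes)
        cds = [iv for g in genes for iv in g.cds]
        n_cds = 0
        for e in truth.by_type("ins", "del"):
            size = len(e.seq) if e.etype == "ins" else e.donor_span
            span = Interval(e.chrom, e.donor_start,
                            max(e.donor_end, e.donor_start + 1))
            if any(span.overlaps(iv) for iv in cds):
                n_cds += 1
                assert size % 3 == 0
        assert n_cds > 0  # the constraint was actually exercised


class TestDepth:
    def _truth_with_cnv(self, ancestor):
        params = EvolutionParams(snp_rate=0.0, indel_rate=0.0, pav_count=0,
                                 cnv_count=3, cnv_len=(1000, 1000),
                                 cnv_copy_weights={3: 1.0}, seed=7)
        return evolve(ancestor, params)[1]

    def test_no_events_zero_noise_flat(self, ancestor_100k):
        params = EvolutionParams(snp_rate=0.0, indel_rate=0.0, pav_count=0,
                                 seed=1)
        _, truth = evolve(ancestor_100k, params)
        track = simulate_depth(ancestor_100k, truth, mean_depth=30.0,
                               noise="none")
        assert all(d == 30.0 for _, d in track.windows)

    def test_copy3_zero_noise(self, ancestor_100k):
        truth = self._truth_with_cnv(ancestor_100k)
        track = simulate_depth(ancestor_100k, truth, mean_depth=30.0,
                               noise="none")
        gains = truth.by_type("cnv_gain")
        for iv, depth in track.windows:
            inside = any(
                e.donor_start <= iv.start and iv.end <= e.donor_end
                for e in gains
            )
            if inside:
                assert depth == 90.0

    def test_windows_tile_without_overlap(self, ancestor_100k):
        truth = self._truth_with_cnv(ancestor_100k)
        track = simulate_depth(ancestor_100k, truth, 30.0, window=250)
        pos = 0
        for iv, _ in track.windows:
            assert iv.start == pos
            pos = iv.end
        assert pos == ancestor_100k.total_length

    def test_poisson_mean_within_bound(self, ancestor_100k):
        params = EvolutionParams(snp_rate=0.0, indel_rate=0.0, pav_count=0,
                                 seed=1)
        _, truth = evolve(ancestor_100k, params)
        track = simulate_depth(ancestor_100k, truth, mean_depth=40.0,
                               window=100, noise="poisson", seed=3)
        depths = np.array([d for _, d in track.windows])
        n = len(depths)  # 1000 windows of Poisson(40)
        sigma = np.sqrt(40.0 / n)
        assert abs(depths.mean() - 40.0) < 4 * sigma


class TestLiftGenes:
    def test_genes_hit_by_segmental_loss_are_dropped(self, genic_ancestor):
        genome, genes = genic_ancestor
        # delete the span of the first gene explicitly
        from tripan.simulate import Event, TruthSet
        victim = genes[0]
        truth = TruthSet("x", [
            Event("pav_loss", victim.chrom, victim.span.start,
                  victim.span.end)
        ])
        lifted = lift_genes(genes, truth)
        ids = {g.gene_id for g in lifted}
        assert victim.gene_id not in ids
        assert len(lifted) == len(genes) - 1

    def test_downstream_genes_shift_by_event_delta(self, genic_ancestor):
        genome, genes = genic_ancestor
        from tripan.simulate import Event, TruthSet
        first = min(genes, key=lambda g: g.span.start)
        truth = TruthSet("x", [Event("pav_gain", first.chrom, 0, 0,
                                     seq="A" * 500)])
        lifted = {g.gene_id: g for g in lift_genes(genes, truth)}
        moved = lifted[first.gene_id]
        assert moved.span.start == first.span.start + 500
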