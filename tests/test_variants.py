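"""Small-variant calling, codon effects, six-category SV rules, spectra."""

import numpy as np
import pytest

from conftest import random_genome
from tripan.align import align_genomes, filter_one_to_one
from tripan.blocks import AlignmentBlock
from tripan.errors import OrderingError
from tripan.genome import GeneModel, GenomeSequence, revcomp, translate
from tripan.intervals import Interval
from tripan.variants import (
    VariantRecord, annotate_effects, call_small_variants, category_counts,
    classify_large_variants, indel_size_spectrum, left_align,
)


def perfect_block(rs, re, qs, qe, strand="+", gaps=None):
    return AlignmentBlock(ref=Interval("chr1", rs, re),
                          qry=Interval("chr1", qs, qe), strand=strand,
                          identity=1.0, gaps=gaps or [])


class TestCallSmallVariants:
    def test_identical_block_no_variants(self, rng):
        g = random_genome(rng, 1000)
        blocks = [perfect_block(0, 1000, 0, 1000)]
        assert call_small_variants(blocks, g, g) == []

    def test_single_substitution(self, rng):
        g = random_genome(rng, 1000)
        seq = g.seq("chr1")
        alt = "A" if seq[500] != "A" else "C"
        q = GenomeSequence("q", [("chr1", seq[:500] + alt + seq[501:])])
        [v] = call_small_variants([perfect_block(0, 1000, 0, 1000)], g, q)
        assert (v.vtype, v.start, v.ref_allele, v.alt_allele) == \
            ("snp", 500, seq[500], alt)

    def test_minus_strand_alleles_on_reference(self, rng):
        g = random_genome(rng, 400)
        seq = g.seq("chr1")
        alt = "A" if seq[100] != "A" else "C"
        mutated = seq[:100] + alt + seq[101:]
        q = GenomeSequence("q", [("chr1", revcomp(mutated))])
        [v] = call_small_variants([perfect_block(0, 400, 0, 400, strand="-")],
                                  g, q)
        assert (v.start, v.ref_allele, v.alt_allele) == (100, seq[100], alt)

    def test_exact_recovery_on_sv_free_simulation(self, sv_free_pair, config):
        """Every planted SNP and indel is recovered exactly: coordinates and
        alleles, with no false positives (unique-anchor alignment is exact)."""
        from tripan.evaluate import truth_small_variants
        blocks = filter_one_to_one(
            align_genomes(sv_free_pair["ref"], sv_free_pair["qry"], config)
        )
        called = call_small_variants(blocks, sv_free_pair["ref"],
                                     sv_free_pair["qry"], config)
        truth = truth_small_variants(sv_free_pair["truth"],
                                     sv_free_pair["ref"])
        key = lambda v: (v.chrom, v.start, v.vtype, v.ref_allele,
                         v.alt_allele)
        assert {key(v) for v in called} == {key(v) for v in truth}

    def test_left_alignment_canonicalizes_repeat_indels(self):
        g = GenomeSequence("g", [("chr1", "ACGTTTTTACGT")])
        v = VariantRecord("chr1", 7, 8, "T", "", "del")
        left_align([v], g)
        assert v.start == 3 and v.ref_allele == "T"


class TestEffects:
    def _genome_with_gene(self, cds="ATGAAATAG", strand="+"):
        pad = "C" * 30
        if strand == "+":
            seq = pad + cds + pad
        else:
            seq = pad + revcomp(cds) + pad
        g = GenomeSequence("g", [("chr1", seq)])
        iv = Interval("chr1", 30, 30 + len(cds))
        gene = GeneModel("gene1", "chr1", strand, [iv], [iv])
        return g, gene

    def test_stop_gain(self):
        g, gene = self._genome_with_gene("ATGAAATAG")
        v = VariantRecord("chr1", 33, 34, "A", "T", "snp")  # AAA -> TAA
        annotate_effects([v], [gene], g)
        assert v.effects == {"stop_gain"}

    def test_stop_loss_and_synonymous_and_nonsynonymous(self):
        g, gene = self._genome_with_gene("ATGAAATAG")
        stop_loss = VariantRecord("chr1", 36, 37, "T", "C", "snp")
        syn = VariantRecord("chr1", 35, 36, "A", "G", "snp")      # AAA->AAG (K)
        nonsyn = VariantRecord("chr1", 34, 35, "A", "C", "snp")   # AAA->ACA
        annotate_effects([stop_loss, syn, nonsyn], [gene], g)
        assert stop_loss.effects == {"stop_loss"}
        assert syn.effects == {"synonymous"}
        assert nonsyn.effects == {"nonsynonymous"}

    def test_minus_strand_stop_gain(self):
        g, gene = self._genome_with_gene("ATGAAATAG", strand="-")
        # genomic = revcomp(CDS): codon2 'AAA' maps to genomic 'TTT' at 33..36;
        # coding A->T means genomic T->A on the last codon2 genomic base
        pos = 35
        v = VariantRecord("chr1", pos, pos + 1, g.seq("chr1")[pos], "A", "snp")
        annotate_effects([v], [gene], g)
        assert v.effects == {"stop_gain"}

    def test_frameshift_and_inframe(self):
        g, gene = self._genome_with_gene("ATGAAATAG")
        fs = VariantRecord("chr1", 33, 35, "AA", "", "del")
        inf = VariantRecord("chr1", 33, 36, "AAA", "", "del")
        annotate_effects([fs, inf], [gene], g)
        assert fs.effects == {"frameshift"}
        assert inf.effects == {"inframe"}

    def test_intergenic(self):
        g, gene = self._genome_with_gene()
        v = VariantRecord("chr1", 2, 3, g.seq("chr1")[2], "T", "snp")
        annotate_effects([v], [gene], g)
        assert v.effects == {"intergenic"}

    def test_boundary_deletion_flagged(self):
        g, gene = self._genome_with_gene("ATGAAATAG")
        v = VariantRecord("chr1", 28, 32, "CCAT", "", "del")
        annotate_effects([v], [gene], g)
        assert v.boundary

    def test_translation_oracle_on_random_cds_snps(self, genic_ancestor):
        """Codon-level annotation agrees with an independent whole-protein
        translation oracle on 1,000 random coding SNPs."""
        genome, genes = genic_ancestor
        rng = np.random.default_rng(5)
        cds_positions = [
            (gene, pos)
            for gene in genes
            for iv in gene.cds
            for pos in range(iv.start, iv.end)
        ]
        picks = rng.choice(len(cds_positions), size=1000, replace=False)
        chrom_seq = {c: s for c, s in genome.chromosomes}
        for idx in picks:
            gene, pos = cds_positions[int(idx)]
            ref = chrom_seq[gene.chrom][pos]
            alt = "ACGT"[(("ACGT".index(ref)) + int(rng.integers(1, 4))) % 4]
            v = VariantRecord(gene.chrom, pos, pos + 1, ref, alt, "snp")
            annotate_effects([v], [gene], genome)
            # oracle: mutate the chromosome, re-extract, translate both
            mut_seq = chrom_seq[gene.chrom][:pos] + alt + \
                chrom_seq[gene.chrom][pos + 1:]
            mut_genome = GenomeSequence("m", [(gene.chrom, mut_seq)])
            p_ref = translate(gene.coding_sequence(genome))
            p_alt = translate(gene.coding_sequence(mut_genome))
            if p_ref == p_alt:
                expect = "synonymous"
            else:
                diff = next(i for i, (a, b) in enumerate(zip(p_ref, p_alt))
                            if a != b)
                if p_alt[diff] == "*":
                    expect = "stop_gain"
                elif p_ref[diff] == "*":
                    expect = "stop_loss"
                else:
                    expect = "nonsynonymous"
            assert v.effects == {expect}, (gene.gene_id, pos, ref, alt)


class TestClassifyLargeVariants:
    def test_requires_sorted_blocks(self):
        blocks = [perfect_block(500, 600, 500, 600),
                  perfect_block(0, 100, 0, 100)]
        with pytest.raises(OrderingError):
            classify_large_variants(blocks)

    def test_within_block_gap_insertion(self):
        b = perfect_block(0, 200, 0, 250, gaps=[(100, 0, 50)])
        classified, _ = classify_large_variants([b])
        [v] = classified
        assert v.category == "insertion" and v.size == 50

    @pytest.mark.parametrize(
        "dr,dq,expected",
        [
            (0, 120, "insertion"),
            (120, 0, "deletion"),
            (30, 200, "insertion"),          # min <= repeat_gap_min
            (200, 320, "repeat_expansion"),  # both > repeat_gap_min
            (320, 200, "repeat_contraction"),
            (-200, 0, "tandem_expansion"),
            (0, -200, "tandem_contraction"),
        ],
    )
    def test_between_block_rule_table(self, dr, dq, expected):
        a = perfect_block(0, 1000, 0, 1000)
        b = perfect_block(1000 + dr, 2000 + dr, 1000 + dq, 2000 + dq)
        classified, unclassified = classify_large_variants([a, b])
        assert [v.category for v in classified] == [expected]
        assert not unclassified

    def test_both_negative_reported_separately(self):
        a = perfect_block(0, 1000, 0, 1000)
        b = perfect_block(800, 1800, 850, 1850)
        classified, unclassified = classify_large_variants([a, b])
        assert classified == [] and len(unclassified) == 1

    def test_category_counts_sum_to_total(self):
        blocks = [perfect_block(0, 1000, 0, 1000),
                  perfect_block(1100, 2000, 1000, 1900),
                  perfect_block(2300, 3000, 2250, 2950)]
        classified, _ = classify_large_variants(blocks)
        counts = category_counts(classified)
        assert sum(counts.values()) == len(classified)


class TestIndelSpectrum:
    def test_empty(self):
        assert indel_size_spectrum([], "cds") == {}

    def test_signed_sizes_by_stratum(self):
        records = [
            VariantRecord("c", 1, 1, "", "ACG", "ins",
                          effects={"inframe"}),
            VariantRecord("c", 10, 12, "AC", "", "del",
                          effects={"frameshift"}),
            VariantRecord("c", 50, 51, "A", "", "del",
                          effects={"intergenic"}),
        ]
        assert indel_size_spectrum(records, "cds") == {-2: 1, 3: 1}
        assert indel_size_spectrum(records, "intergenic") == {-1: 1}
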