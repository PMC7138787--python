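"""Scenario builders and the end-to-end demo pipeline.

Each scenario fixes the study conditions for one analysis:

* **trio** — a 1 Mb ancestor with 120 planted genes and three descendants
  (star phylogeny; 0.5% SNPs, small indels, 10 segmental gains + 10 losses
  of 1-5 kb per branch). Pivot-branch events avoid gene bodies so the
  reference gene models stay intact.
* **sv pair** — 500 kb, five tandem duplications on each side plus ten
  plain segmental indels on the query, for the six-category classifier.
* **cnv** — 1 Mb with thirty copy-0/copy-3 events of 1-3 kb and a Poisson
  depth track at 40x in 100 bp windows.
* **purifying** — 300 kb, gene-dense, indels in coding sequence restricted
  to multiples of three (the period-3 indel spectrum).

``run_demo`` executes every stage, returns a scorecard of truth-recovery
metrics, and optionally writes the standard artifacts (FASTA/GFF3/coords/
BED/VCF/JSON) to a directory. Everything is deterministic in the seed.
"""

from __future__ import annotations

import json
import os
import sys

import numpy as np

from . import evaluate, io
from .align import align_genomes, dedup_contained, filter_one_to_one
from .config import DEFAULT_CONFIG, ThresholdConfig
from .genome import GenomeSequence
from .intervals import Interval
from .pangenome import (
    build_pangenome, classify_gene_membership, gene_class_counts, pan_fractions,
)
from .pav_cnv import call_cnv, call_pav_absent_in_query, call_pav_present_in_query
from .simulate import (
    EvolutionParams, TruthSet, evolve, lift_genes, plant_genes,
    simulate_ancestor, simulate_depth, write_truth_tsv,
)
from .stats import fisher_enrichment
from .variants import (
    annotate_effects, call_small_variants, category_counts,
    classify_large_variants, indel_size_spectrum,
)

GENOMES = ("SAT", "RUF", "NIV")


def _seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)]


# -- scenarios --------------------------------------------------------------

def trio_scenario(seed: int, length: int = 1_000_000, n_genes: int = 120):
    """Ancestor + three descendants with genes, truth sets, lifted genes."""
    s = _seeds(seed, 5)
    ancestor = simulate_ancestor(length, gc=0.43, seed=s[0])
    ancestor, genes = plant_genes(ancestor, n_genes, exons_per_gene=2, seed=s[1])
    protected = [g.span for g in genes]
    genomes: dict[str, GenomeSequence] = {}
    truths: dict[str, TruthSet] = {}
    for name, branch_seed, protect in (
        ("SAT", s[2], protected), ("RUF", s[3], None), ("NIV", s[4], None)
    ):
        params = EvolutionParams(seed=branch_seed)
        genomes[name], truths[name] = evolve(
            ancestor, params, genome_id=name, protected=protect
        )
    genes_by_genome = {
        name: lift_genes(genes, truths[name]) for name in GENOMES
    }
    return {
        "ancestor": ancestor, "ancestor_genes": genes, "genomes": genomes,
        "truths": truths, "genes": genes_by_genome,
    }


def align_trio(trio, config: ThresholdConfig = DEFAULT_CONFIG):
    """The three pairwise one-to-one alignment sets (pivot as reference
    against each wild genome; A as reference against B)."""
    g = trio["genomes"]
    return {
        ("SAT", "RUF"): filter_one_to_one(align_genomes(g["SAT"], g["RUF"], config)),
        ("SAT", "NIV"): filter_one_to_one(align_genomes(g["SAT"], g["NIV"], config)),
        ("RUF", "NIV"): filter_one_to_one(align_genomes(g["RUF"], g["NIV"], config)),
    }


def sv_pair_scenario(seed: int, length: int = 500_000):
    """Reference and query with 5 tandem gains each + 10 query indels."""
    s = _seeds(seed, 3)
    ancestor = simulate_ancestor(length, gc=0.43, seed=s[0])
    ref_params = EvolutionParams(
        snp_rate=0.001, indel_rate=1e-4, pav_count=0, cnv_count=5,
        cnv_len=(600, 1500), cnv_copy_weights={2: 1.0}, seed=s[1],
    )
    qry_params = EvolutionParams(
        snp_rate=0.001, indel_rate=1e-4, pav_count=10, pav_len=(100, 1000),
        cnv_count=5, cnv_len=(600, 1500), cnv_copy_weights={2: 1.0}, seed=s[2],
    )
    ref, ref_truth = evolve(ancestor, ref_params, genome_id="svref")
    qry, qry_truth = evolve(ancestor, qry_params, genome_id="svqry")
    return {"ancestor": ancestor, "ref": ref, "qry": qry,
            "ref_truth": ref_truth, "qry_truth": qry_truth}


def cnv_scenario(seed: int, length: int = 1_000_000, n_events: int = 30,
                 mean_depth: float = 40.0):
    """Depth track with planted copy-0 / copy-3 events of 1-3 kb."""
    s = _seeds(seed, 3)
    ancestor = simulate_ancestor(length, gc=0.43, seed=s[0])
    params = EvolutionParams(
        snp_rate=0.0, indel_rate=0.0, pav_count=0, cnv_count=n_events,
        cnv_len=(1000, 3000), cnv_copy_weights={0: 0.5, 3: 0.5}, seed=s[1],
    )
    derived, truth = evolve(ancestor, params, genome_id="cnvqry")
    depth = simulate_depth(ancestor, truth, mean_depth=mean_depth,
                           window=100, noise="poisson", seed=s[2])
    return {"ancestor": ancestor, "derived": derived, "truth": truth,
            "depth": depth}


def purifying_scenario(seed: int, length: int = 300_000, n_genes: int = 120):
    """Gene-dense pair whose coding indels are multiples of three."""
    s = _seeds(seed, 3)
    ancestor = simulate_ancestor(length, gc=0.43, seed=s[0])
    ancestor, genes = plant_genes(ancestor, n_genes, exons_per_gene=1,
                                  cds_len_range=(600, 1200), seed=s[1])
    params = EvolutionParams(
        snp_rate=0.002, indel_rate=2e-3, pav_count=0, purifying=True, seed=s[2],
    )
    derived, truth = evolve(ancestor, params, genome_id="purified",
                            genes=genes)
    return {"ancestor": ancestor, "genes": genes, "derived": derived,
            "truth": truth}


def enrichment_scenario(seed: int, n_universe: int = 1000, n_terms: int = 20):
    """Synthetic annotations with one genuinely enriched term."""
    rng = np.random.default_rng(_seeds(seed, 1)[0])
    universe = [f"g{i:04d}" for i in range(n_universe)]
    annotations: dict[str, list[str]] = {g: [] for g in universe}
    for t in range(n_terms):
        members = rng.choice(n_universe, size=80, replace=False)
        for m in members:
            annotations[universe[m]].append(f"TERM{t:02d}")
    # gene set: half drawn from TERM00 members, half random
    term0 = [g for g in universe if "TERM00" in annotations[g]]
    others = [g for g in universe if "TERM00" not in annotations[g]]
    gene_set = list(rng.choice(term0, size=40, replace=False)) + list(
        rng.choice(others, size=40, replace=False)
    )
    return {"universe": universe, "annotations": annotations,
            "gene_set": gene_set, "planted_term": "TERM00"}


# -- demo -------------------------------------------------------------------

def _log(manifest: list[dict], stage: str, **info):
    entry = {"stage": stage, **info}
    manifest.append(entry)
    print(json.dumps(entry), file=sys.stderr)


def run_demo(seed: int, outdir: str | None = None,
             config: ThresholdConfig = DEFAULT_CONFIG,
             trio_length: int = 1_000_000,
             trio_genes: int | None = None,
             write_genomes: bool = False) -> dict:
    """Simulate -> align -> pangenome -> variants -> SV -> PAV -> CNV ->
    spectrum -> enrichment; returns the truth-recovery scorecard."""
    manifest: list[dict] = []
    scorecard: dict = {"seed": seed}
    if outdir:
        os.makedirs(outdir, exist_ok=True)

    # --- trio & pan-genome (gene count scales with genome size)
    if trio_genes is None:
        trio_genes = max(20, trio_length // 8_500)
    trio = trio_scenario(seed, length=trio_length, n_genes=trio_genes)
    _log(manifest, "simulate_trio", length=trio_length,
         events={g: len(t.events) for g, t in trio["truths"].items()})
    alignments = align_trio(trio, config)
    _log(manifest, "align", blocks={f"{a}-{b}": len(v)
                                    for (a, b), v in alignments.items()})
    lengths = {g: trio["genomes"][g].chrom_lengths for g in GENOMES}
    segments, stats = build_pangenome(
        alignments[("SAT", "RUF")], alignments[("SAT", "NIV")],
        alignments[("RUF", "NIV")], lengths, names=GENOMES, config=config,
    )
    membership = classify_gene_membership(
        trio["genes"], segments, names=GENOMES,
        presence_frac=config.gene_presence_frac,
    )
    stats.gene_counts = gene_class_counts(
        [m for m in membership if m.owner == "SAT"]
    )
    truth_pan = evaluate.pan_truth(trio["ancestor"], trio["truths"])
    scorecard["pangenome"] = {
        "measured": {
            "pan_bp": stats.pan_bp, "core_bp": stats.core_bp,
            "dispensable_bp": stats.dispensable_bp,
            **{f"specific_bp_{g}": stats.specific_bp[g] for g in GENOMES},
        },
        "truth": truth_pan,
        "fractions": pan_fractions(stats),
        "rel_err": {
            key: abs(getattr(stats, key) - truth_pan[key]) / truth_pan[key]
            for key in ("core_bp", "dispensable_bp")
        },
    }
    spec_meas = sum(stats.specific_bp.values())
    spec_truth = sum(truth_pan[f"specific_bp_{g}"] for g in GENOMES)
    scorecard["pangenome"]["rel_err"]["specific_bp"] = (
        abs(spec_meas - spec_truth) / spec_truth if spec_truth else 0.0
    )
    # gene membership vs truth: a gene is truly present on a branch when at
    # least the presence fraction of its CDS bp escaped segmental deletion
    # (the same contract the measurement applies to alignment coverage)
    truth_class = {}
    for gene in trio["ancestor_genes"]:
        n = 0
        for g in GENOMES:
            deleted = sum(
                iv.intersection_bp(d)
                for iv in gene.cds
                for d in trio["truths"][g].deleted_intervals()
            )
            if 1 - deleted / gene.cds_length >= config.gene_presence_frac:
                n += 1
        truth_class[gene.gene_id] = {3: "core", 2: "dispensable",
                                     1: "specific"}.get(n, "lost")
    measured_class = {m.gene_id: m.klass for m in membership if m.owner == "SAT"}
    scored = [g for g in truth_class if g in measured_class
              and truth_class[g] != "lost"]
    agree = sum(truth_class[g] == measured_class[g] for g in scored)
    scorecard["gene_membership"] = {
        "agree": agree, "total": len(scored),
        "accuracy": agree / len(scored) if scored else 1.0,
        "counts": stats.gene_counts,
    }
    _log(manifest, "pangenome", **scorecard["pangenome"]["measured"])

    # --- small variants on an SV-free pair (exact-recovery conditions)
    s = _seeds(seed + 101, 3)
    anc_sv_free = simulate_ancestor(100_000, gc=0.43, seed=s[0])
    anc_sv_free, sv_free_genes = plant_genes(anc_sv_free, 20, seed=s[1])
    qry_sv_free, truth_sv_free = evolve(
        anc_sv_free,
        EvolutionParams(pav_count=0, cnv_count=0, seed=s[2]),
        genome_id="pairqry",
    )
    pair_blocks = filter_one_to_one(
        align_genomes(anc_sv_free, qry_sv_free, config)
    )
    variants = call_small_variants(pair_blocks, anc_sv_free, qry_sv_free, config)
    annotate_effects(variants, sv_free_genes, anc_sv_free)
    scorecard["small_variants"] = {
        "snp": evaluate.small_variant_scores(variants, truth_sv_free,
                                             anc_sv_free, vtypes=("snp",)),
        "indel": evaluate.small_variant_scores(
            variants, truth_sv_free, anc_sv_free, vtypes=("ins", "del")
        ),
    }
    _log(manifest, "small_variants", **scorecard["small_variants"]["snp"])

    # --- six-category structural variants
    sv = sv_pair_scenario(seed + 202)
    sv_blocks = dedup_contained(align_genomes(sv["ref"], sv["qry"], config,
                                              mode="sv"))
    classified, unclassified = classify_large_variants(sv_blocks, config)
    expected = evaluate.expected_large_variants(sv["ref_truth"],
                                                sv["qry_truth"])
    scorecard["large_variants"] = {
        **evaluate.sv_category_scores(classified, expected),
        "counts": category_counts(classified),
        "n_classified": len(classified),
        "n_unclassified": len(unclassified),
    }
    _log(manifest, "large_variants", **scorecard["large_variants"]["counts"])

    # --- PAV on the trio (RUF vs SAT and NIV vs SAT)
    pav_out = {}
    for qname, klass10, klass01 in (("RUF", "RS10", "RS01"),
                                    ("NIV", "NS10", "NS01")):
        blocks = alignments[("SAT", qname)]
        present, q_genes = call_pav_present_in_query(
            trio["genomes"][qname], blocks, trio["genomes"]["SAT"], config,
            klass=klass10, genes=trio["genes"][qname],
        )
        absent, r_genes = call_pav_absent_in_query(
            trio["genomes"]["SAT"], blocks, config, klass=klass01,
            genes=trio["genes"]["SAT"],
        )
        # planted gains on the query are present-in-query truth
        gains = [
            Interval(e.chrom, e.recipient_start, e.recipient_end)
            for e in trio["truths"][qname].by_type("pav_gain")
        ]
        losses_on_sat = []
        for e in trio["truths"][qname].by_type("pav_loss"):
            lo = trio["truths"]["SAT"].lift(e.chrom, e.donor_start)
            hi = trio["truths"]["SAT"].lift(e.chrom, e.donor_end)
            # skip spans the pivot itself (partly) deleted: they are not
            # cleanly present-in-pivot and have no single expected record
            if hi - lo >= e.donor_span - config.pav_min_len:
                losses_on_sat.append(Interval(e.chrom, lo, hi))
        pav_out[qname] = {
            "present": present, "absent": absent,
            "query_specific_genes": q_genes, "ref_specific_genes": r_genes,
            "gain_recovery": evaluate.pav_recovery(present, gains),
            "loss_recovery": evaluate.pav_recovery(absent, losses_on_sat),
        }
    scorecard["pav"] = {
        q: {"n_present": len(v["present"]), "n_absent": len(v["absent"]),
            "gain_recovery": v["gain_recovery"],
            "loss_recovery": v["loss_recovery"]}
        for q, v in pav_out.items()
    }
    _log(manifest, "pav", **{q: scorecard["pav"][q]["gain_recovery"]
                             for q in pav_out})

    # --- CNV from read depth
    cnv = cnv_scenario(seed + 303)
    regions = call_cnv(cnv["depth"], config)
    scorecard["cnv"] = evaluate.cnv_scores(regions, cnv["truth"])
    _log(manifest, "cnv", **scorecard["cnv"])

    # --- period-3 indel spectrum under purifying selection
    pur = purifying_scenario(seed + 404)
    pur_blocks = filter_one_to_one(
        align_genomes(pur["ancestor"], pur["derived"], config)
    )
    pur_variants = call_small_variants(pur_blocks, pur["ancestor"],
                                       pur["derived"], config)
    annotate_effects(pur_variants, pur["genes"], pur["ancestor"])
    cds_spec = indel_size_spectrum(pur_variants, "cds")
    scorecard["indel_spectrum"] = {
        "cds": {str(k): v for k, v in cds_spec.items()},
        "all_multiples_of_three": bool(cds_spec) and all(
            size % 3 == 0 for size in cds_spec
        ),
    }
    _log(manifest, "indel_spectrum",
         multiples_of_3=scorecard["indel_spectrum"]["all_multiples_of_three"])

    # --- enrichment
    enr = enrichment_scenario(seed + 505)
    results = fisher_enrichment(enr["gene_set"], enr["universe"],
                                enr["annotations"])
    planted = next(r for r in results if r.term == enr["planted_term"])
    scorecard["enrichment"] = {
        "planted_term": planted.term, "p": planted.p, "q": planted.q,
        "top_term": results[0].term,
        "planted_is_top": results[0].term == enr["planted_term"],
    }
    _log(manifest, "enrichment", planted_p=planted.p)

    if outdir:
        _write_outputs(outdir, trio, alignments, segments, stats, membership,
                       variants, anc_sv_free, classified, pav_out, regions,
                       scorecard, manifest, write_genomes, config)
    return scorecard


def _write_outputs(outdir, trio, alignments, segments, stats, membership,
                   variants, variant_ref, classified, pav_out, cnv_regions,
                   scorecard, manifest, write_genomes, config):
    join = lambda name: os.path.join(outdir, name)
    if write_genomes:
        for name, genome in trio["genomes"].items():
            io.write_fasta(genome, join(f"{name}.fa"))
        io.write_gff3(trio["genes"]["SAT"], join("SAT.genes.gff3"))
    for name, truth in trio["truths"].items():
        write_truth_tsv(truth, join(f"{name}.truth.tsv"))
    for (a, b), blocks in alignments.items():
        rows = []
        for blk in blocks:
            rows.extend(blk.split_at_large_gaps(config.small_variant_max))
        io.write_coords(rows, join(f"{a}_{b}.coords"))
    io.write_bed(
        ((seg.interval, seg.klass, seg.owner) for seg in segments),
        join("pansegments.bed"),
    )
    with open(join("panstats.json"), "w") as fh:
        json.dump(
            {
                "pan_bp": stats.pan_bp, "core_bp": stats.core_bp,
                "dispensable_bp": stats.dispensable_bp,
                "specific_bp": stats.specific_bp,
                "pairwise_pan_bp": {
                    f"{a}-{b}": v for (a, b), v in stats.pairwise_pan_bp.items()
                },
                "gene_counts": stats.gene_counts,
                "fractions": pan_fractions(stats),
            },
            fh, indent=2,
        )
    with open(join("gene_membership.tsv"), "w") as fh:
        fh.write("gene_id\towner\tklass\n")
        for m in membership:
            fh.write(f"{m.gene_id}\t{m.owner}\t{m.klass}\n")
    io.write_vcf(variants, variant_ref, join("small_variants.vcf"))
    with open(join("large_variants.tsv"), "w") as fh:
        fh.write("category\tref_chrom\tref_start\tref_end\tsize\n")
        for v in classified:
            fh.write(f"{v.category}\t{v.ref_anchor.chrom}\t"
                     f"{v.ref_anchor.start}\t{v.ref_anchor.end}\t{v.size}\n")
    for qname, out in pav_out.items():
        rows = [(r.interval, r.klass, r.length,
                 "" if r.best_realignment_identity is None
                 else f"{r.best_realignment_identity:.4f}")
                for r in out["present"] + out["absent"]]
        io.write_bed(rows, join(f"pav_{qname}.bed"))
    io.write_bed(
        ((r.interval, f"{r.norm_depth:.3f}", r.call) for r in cnv_regions),
        join("cnv_regions.bed"),
    )
    with open(join("scorecard.json"), "w") as fh:
        json.dump(scorecard, fh, indent=2, default=str)
    with open(join("manifest.jsonl"), "w") as fh:
        for entry in manifest:
            fh.write(json.dumps(entry, default=str) + "\n")
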