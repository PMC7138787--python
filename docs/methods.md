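# Methods

`tripan` re-implements a tri-genome comparative analysis — pairwise
whole-genome alignment, pan-genome core/dispensable/specific
classification, small-variant calling with effect annotation, six-category
structural-variant typing, presence-absence (PAV) and read-depth
copy-number (CNV) calling, and Fisher-exact enrichment — and exercises the
whole pipeline on a synthetic three-genome evolution simulator that emits a
complete machine-readable truth set for every planted event. This note
documents the models, the thresholds, the numerical choices, and what the
synthetic benchmark does and does not demonstrate.

## Coordinates and containers

All internal coordinates are 0-based half-open. The only conversions to the
1-based inclusive conventions of GFF3, show-coords and VCF happen in
`tripan.io`, so every off-by-one lives at one file boundary. An
`AlignmentBlock` stores both genome intervals ascending plus a strand flag;
on the minus strand the reference walks left-to-right while the query walks
right-to-left. Internal indels are kept as an ordered gap list
`(ref_offset, ref_gap_len, qry_gap_len)` satisfying
`ref_len + Σqry_gap = qry_len + Σref_gap`. The show-coords tab dialect
cannot carry gap structure; when coverage semantics must survive
serialization, blocks are split at gaps larger than the small-variant bound
so unaligned spans become inter-row space.

## The aligner

Anchors are exact canonical k-mer matches (default k = 21, odd, 11–31). In
the default regime only k-mers unique in both genomes anchor, which makes
the anchor set exactly reproducible by a brute-force hash join and keeps
repeats out of the chains. Anchors are collapsed to maximal diagonal runs,
then chained per (reference chromosome, query chromosome, strand) with a
bounded-lookback weighted longest-increasing-subsequence (weight = anchored
bp, small gap penalty). Runs may overlap by up to k−1 bp from k-mer span
extension; the overlap is tolerated in the DP and trimmed at block
construction. Chains are extracted iteratively (best first, runs consumed
once), and chains anchoring fewer than `min_chain_len` = 100 bp are
dropped. Interstices larger than `max_bridge` = 10 kb are never bridged and
split chains into separate blocks.

Interstices between consecutive runs are filled as follows:

* equal lengths — column-by-column comparison, so substitutions are placed
  exactly, with no indel hypothesis;
* one dominant indel (length difference ≥ 20 bp) — greedy end-anchored
  extension (tolerating isolated mismatches) with a single clean gap in the
  middle. A global aligner is deliberately avoided here: minimizing edit
  distance threads the short side through the long side to buy back
  mismatches, which shreds the gap into dozens of spurious micro-indels and
  fakes coverage where there is none;
* near-balanced interstices — edlib global alignment, accepted only if the
  edit distance in excess of the pure length difference stays below 0.3 per
  short-side base. Unrelated sequence (excess ≈ 0.5) is recorded as an
  unaligned deletion+insertion pair instead.

Forced-match stretches with less than 50% identity (over > 4 bp) or less
than 75% (over > 30 bp) are likewise demoted to unaligned sequence. Block
identity is matched columns over all columns (mismatches and gap columns
count against it).

A second regime (`sv` mode) admits k-mers occurring up to three times per
genome and keeps structural differences between blocks rather than bridging
them. This is what makes tandem duplications visible: the duplicated unit
anchors each copy, producing two blocks that overlap on exactly one genome
— the signature the six-category classifier keys on. Unique-in-both
anchoring can never produce that signature, which is why the SV path
deviates from the default.

One-to-one filtering is greedy by identity-weighted aligned bp with
trimming: a candidate overlapping accepted coverage is cut back to its
largest uncovered piece on each genome. The result covers no reference or
query position twice. Before SV classification a gentler containment-dedup
is used instead (drop blocks nested in another block on both genomes),
because partial overlaps are themselves the tandem signal there.

## Pan-genome classification

"Aligned" coverage excludes within-block gap spans longer than the
small-variant bound (10 bp): a 2 kb deletion inside one block is an
absence, a 3 bp indel is not. Every base of every genome is classified by
how many partners cover it (core = both, dispensable = exactly one,
specific = none). Pan-genome size is pivot-centric: the whole pivot genome,
plus A-genome bases unaligned to the pivot, plus B-genome bases unaligned
to both — so B sequence shared with A but absent from the pivot is owned by
A once, and `pan = core + dispensable + Σ specific` holds exactly on every
run. How shared-but-not-pivot sequence should be deduplicated is genuinely
underdetermined; this ownership rule is one consistent choice, asserted as
an invariant rather than claimed as a reconstruction.

A gene is *present* in another genome when at least `gene_presence_frac`
(default 0.8) of its CDS bp lies in segments aligned to that genome;
membership classes follow the same core/dispensable/specific logic. The
absence-call gene rule uses 0.5 of CDS bp and the specific-gene rule 0.8,
both configurable, because both conventions are in common use.

## Variants

Small variants (≤ 10 bp) are read directly off block structure: one SNP per
mismatched column, one indel per gap run, alleles on the reference strand,
then left-aligned through repeat context (standard VCF normalization).
Effects use the standard code (stops TAA/TAG/TGA): coding SNPs are
synonymous/nonsynonymous/stop_gain/stop_loss by strand-aware codon
comparison; coding indels are frameshift unless divisible by three; indels
straddling a CDS boundary keep their mod-3 call and carry a `boundary`
flag; everything non-coding (introns included) is intergenic. Stop gain,
stop loss and frameshift together constitute the large-effect class.

Variants larger than 10 bp are classified from alignment-gap geometry.
Within-block gaps are insertions/deletions by which side holds the extra
bases. Between consecutive blocks, with `dr` the reference gap and `dq` the
strand-adjusted query gap: both non-negative with `min(dr,dq) ≤ 50`
(`repeat_gap_min`) → insertion/deletion by the sign of `dq−dr`; both
non-negative with `min > 50` → repeat expansion/contraction; `dr < 0 ≤ dq`
(reference overlap) → tandem expansion; `dq < 0 ≤ dr` → tandem contraction;
both negative → unclassified, reported separately. Overlaps smaller than k
are clamped to zero first — they are k-mer-extension noise, not tandem
signal. These decision rules are this package's committed reconstruction of
a standard assembly-vs-assembly SV typology; the observable contract is the
category vocabulary and the bookkeeping identity (six category counts sum
to the classified total).

## PAV and CNV

Presence-in-query: query intervals with zero one-to-one coverage, longer
than 100 bp (strict), are realigned against the whole reference with the
anchor aligner; a record survives only if its best-hit identity is ≤ 0.95
or it has no hit at all, so diverged or duplicated copies are not miscalled
as presence/absence. The identity filter applies to the best hit.
Absence-in-query: uncovered reference intervals merged across gaps
strictly smaller than 500 bp, reported above 100 bp. The historical
contamination screen against an external nucleotide database is replaced
by an exclusion-BED hook (no external database at desk scale).

CNV calling takes a windowed depth track, normalizes by the weighted genome
mean (calls are therefore invariant under uniform rescaling), flags windows
outside `[cnv_low, cnv_high]`, merges same-direction runs, and reports runs
≥ 500 bp. The published-style bounds "< 1.2 or > 1.8 of the mean" are
internally inconsistent for losses (a normal 1.0× window is below 1.2), so
the defaults are the symmetric pair 0.5 / 1.5; the verbatim pair remains
available via `ThresholdConfig.printed_cnv_thresholds()`. Genes with more
than 80% of exon bp inside CNV regions are the affected-gene candidates,
with direction gain/loss/both.

## Enrichment

One-sided (over-representation) Fisher exact tests per term — the p-value
is the upper hypergeometric tail, computed via scipy — with
Benjamini–Hochberg control across tested terms (statsmodels). Sidedness is
a convention choice: over-representation is the universal default for
GO-style gene-set questions. The test suite checks the p-values against an
exact integer/Fraction enumeration for every 2×2 table with N ≤ 60 and the
q-values against a direct implementation of the step-up formula.

## The simulator

`simulate_ancestor` draws an i.i.d. genome at a target GC (default 0.43, a
typical grass-genome value). `plant_genes` writes intact ORFs (ATG start,
single stop, no internal stop, length divisible by three, optionally
multi-exon) into the sequence. `evolve` derives one descendant per branch
of a star phylogeny with, by default, 0.5% SNPs, small indels at 5×10⁻⁴
per bp (geometric lengths, p = 0.35, capped at 10 bp), and twenty
segmental events of 1–5 kb per branch, half novel-sequence gains and half
losses; copy-number events (tandem, copies 0/2/3, ≥ 500 bp) are enabled by
the scenarios that study them. Event placement is rejection-sampled with a
50 bp spacing buffer and fails loudly after 1,000 retries — silent overlap
would corrupt the replay oracle. Every simulation asserts the replay
invariant: applying the truth set to the ancestor reproduces the derived
genome byte-for-byte. The pivot branch excludes events overlapping planted
gene bodies so reference gene models keep valid ORFs for effect
annotation; gene coordinates are lifted through each branch's offset map,
and genes overlapping segmental deletions are dropped from that genome.

Depth tracks place windows (default 100 bp) on the donor genome's
coordinates with window depth centred at `mean_depth × copy_number` (copy
numbers from the truth set's CNV events; 0 for losses) under Poisson noise
by default, negative binomial optionally, or noise-free for exactness
tests. Presence/absence truth is evaluated at segmental resolution: only
PAV/CNV losses remove presence, because sub-10 bp deletions sit below the
coverage resolution the measurement itself uses.

What the simulator does *not* emulate — and hence what green tests do not
show about real genomes: repeats and transposable elements (anchoring on
real genomes is far harder), inversions and translocations, heterozygosity
and read-level sequencing error, GC-dependent coverage bias, and realistic
gene structure (UTRs, alternative splicing). The i.i.d. background makes
unique-k-mer anchoring nearly complete; on repeat-rich genomes the
coordinate-file import path (external aligner output) is the intended
route.

## Study conditions and problem sizes

The standard scenarios are: a 3×1 Mb trio (pan-genome and gene-membership
recovery; ~117 genes), a 100 kb SV-free pair (exact small-variant
recovery), a 500 kb SV pair with five tandem gains per side and ten plain
segmental indels on the query (category recovery — reference-side gains
present as query tandem contractions), a 1 Mb / 30-event CNV track at 40×,
and a 300 kb gene-dense purifying pair (period-3 spectrum). These sizes
give every estimator hundreds-to-thousands of events while keeping the
full pipeline runnable in well under a minute per scenario on one core.

## Numerical and tie-break choices

* "distance < 500 bp" and "> 100 bp" are strict inequalities.
* Half-up rounding at printed precision for reported percentages.
* Greedy one-to-one admission order is decreasing identity×bp; ties fall
  back to input order (deterministic).
* Sliced blocks inherit the parent block's identity (per-window mismatch
  counts are not retained).
* Truth matching tolerances: ±50 bp for PAV breakpoints (anchor
  granularity bounds placement), reciprocal overlap ≥ 0.5 for CNV regions,
  locus overlap for SV categories; small variants within 100 bp of a
  planted structural event are excluded from precision/recall, since their
  placement there is alignment convention rather than caller quality.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; derived seeds are generated with
  `SeedSequence` and kept below 2³¹.

## Known limitations

Tandem-array copy numbers above three, nested events, and SVs closer
together than the anchor spacing are not resolved. The one-to-one filter
is greedy, not optimal; the tests bound it within 5% of the exhaustive
optimum on small instances. PAV realignment uses the anchor aligner, so a
homolog shattered below k-mer resolution would not be recognized (and the
segment would then be called presence/absence). Enrichment is exercised on
synthetic annotations only; no ontology structure is modelled.
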