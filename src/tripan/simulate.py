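"""Synthetic three-genome evolution with machine-readable truth.

An ancestral haploid genome is simulated, protein-coding genes with intact
ORFs are written into it, and descendants are derived independently (star
phylogeny) by planting SNPs, small indels (geometric lengths), segmental
insertions/deletions (PAV events, >= 100 bp) and tandem copy-number events
(>= 500 bp, copies 0/2/3). Every event is recorded with donor (ancestor) and
recipient (derived) coordinates; replaying the truth set on the ancestor
reproduces the derived genome byte for byte, which every downstream recovery
test asserts.

Events never overlap on the donor (rejection-sampled placement with a
spacing buffer; loud failure after too many retries). A purifying mode
restricts indels that fall in coding sequence to lengths divisible by three,
emulating selection against frameshifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError, PlacementError, SimulationError
from .genome import GeneModel, GenomeSequence, revcomp
from .intervals import Interval

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]

EVENT_TYPES = ("snp", "ins", "del", "pav_gain", "pav_loss", "cnv_gain", "cnv_loss")


@dataclass
class Event:
    etype: str
    chrom: str
    donor_start: int
    donor_end: int           # == donor_start for pure insertions
    seq: str = ""            # inserted sequence, or alt base for a SNP
    ref: str = ""            # replaced base(s): SNP ref allele / deleted span
    copies: int = 1          # total copies for cnv_gain (2 or 3)
    recipient_start: int = -1
    recipient_end: int = -1

    @property
    def donor_span(self) -> int:
        return self.donor_end - self.donor_start

    def length_delta(self) -> int:
        if self.etype in ("ins", "pav_gain"):
            return len(self.seq)
        if self.etype in ("del", "pav_loss", "cnv_loss"):
            return -self.donor_span
        if self.etype == "cnv_gain":
            return (self.copies - 1) * self.donor_span
        return 0


@dataclass
class TruthSet:
    genome_id: str
    events: list[Event] = field(default_factory=list)

    def by_type(self, *etypes: str) -> list[Event]:
        return [e for e in self.events if e.etype in etypes]

    def deleted_intervals(self, include_small: bool = False) -> list[Interval]:
        """Donor spans absent from the derived genome.

        By default only segmental losses (PAV/CNV) count: small deletions
        sit below presence/absence resolution, matching how alignment
        coverage bridges sub-threshold gaps.
        """
        etypes = ("del", "pav_loss", "cnv_loss") if include_small else (
            "pav_loss", "cnv_loss")
        return [
            Interval(e.chrom, e.donor_start, e.donor_end)
            for e in self.by_type(*etypes)
        ]

    def replay(self, ancestor: GenomeSequence) -> GenomeSequence:
        """Re-apply all events to the ancestor (the truth-set invariant)."""
        chroms = []
        for name, seq in ancestor.chromosomes:
            evs = sorted(
                (e for e in self.events if e.chrom == name),
                key=lambda e: (e.donor_start, e.donor_end),
            )
            parts, pos = [], 0
            for e in evs:
                if e.donor_start < pos:
                    raise SimulationError(
                        f"overlapping events on {name} at {e.donor_start}"
                    )
                parts.append(seq[pos : e.donor_start])
                if e.etype == "snp":
                    parts.append(e.seq)
                    pos = e.donor_start + 1
                elif e.etype in ("ins", "pav_gain"):
                    parts.append(e.seq)
                    pos = e.donor_start
                elif e.etype in ("del", "pav_loss", "cnv_loss"):
                    pos = e.donor_end
                elif e.etype == "cnv_gain":
                    parts.append(seq[e.donor_start : e.donor_end] * e.copies)
                    pos = e.donor_end
                else:
                    raise SimulationError(f"unknown event type {e.etype}")
            parts.append(seq[pos:])
            chroms.append((name, "".join(parts)))
        return GenomeSequence(genome_id=self.genome_id, chromosomes=chroms)

    def offset_map(self, chrom: str):
        """Sorted (donor_pos, cumulative_delta) steps for coordinate lifting."""
        steps = [(0, 0)]
        delta = 0
        for e in sorted(
            (e for e in self.events if e.chrom == chrom),
            key=lambda e: e.donor_start,
        ):
            delta += e.length_delta()
            steps.append((e.donor_end, delta))
        return steps

    def lift(self, chrom: str, pos: int) -> int:
        """Donor coordinate -> recipient coordinate (positions inside deleted
        spans snap to the deletion point)."""
        delta = 0
        for e in sorted(
            (e for e in self.events if e.chrom == chrom),
            key=lambda e: e.donor_start,
        ):
            if e.donor_start >= pos:
                break
            if e.donor_end > pos:  # inside a deleted/duplicated span
                if e.etype in ("del", "pav_loss", "cnv_loss"):
                    return e.donor_start + delta
                # cnv_gain keeps the first copy in place
                return pos + delta
            delta += e.length_delta()
        return pos + delta


@dataclass(frozen=True)
class EvolutionParams:
    """Per-branch mutation load.

    Defaults are the standard trio conditions used throughout the analyses:
    0.5% SNP divergence, small indels at a tenth of that with geometric
    lengths (p=0.35, capped at the small-variant bound), and twenty
    segmental presence/absence events of 1-5 kb split evenly between gains
    and losses. Copy-number events are off by default and switched on by the
    scenarios that study them.
    """

    snp_rate: float = 0.005
    indel_rate: float = 5e-4
    indel_geom_p: float = 0.35
    indel_max: int = 10
    pav_count: int = 20
    pav_len: tuple[int, int] = (1000, 5000)
    pav_gain_frac: float = 0.5
    cnv_count: int = 0
    cnv_len: tuple[int, int] = (1000, 3000)
    cnv_copy_weights: dict = field(
        default_factory=lambda: {0: 0.5, 2: 0.25, 3: 0.25}
    )
    min_event_spacing: int = 50
    purifying: bool = False
    seed: int = 0

    def __post_init__(self):
        for rate in (self.snp_rate, self.indel_rate):
            if not 0.0 <= rate <= 1.0:
                raise ParameterError(f"rate {rate} outside [0, 1]")
        if self.pav_count and self.pav_len[0] < 100:
            raise ParameterError("PAV lengths must be >= 100 bp")
        if self.cnv_count and self.cnv_len[0] < 500:
            raise ParameterError("CNV lengths must be >= 500 bp")
        if not all(c in (0, 2, 3) for c in self.cnv_copy_weights):
            raise ParameterError("CNV copies must be 0 (loss), 2 or 3")


# -- ancestor ---------------------------------------------------------------

def simulate_ancestor(length: int, gc: float = 0.43, seed: int = 0,
                      n_chromosomes: int = 1,
                      genome_id: str = "ancestor") -> GenomeSequence:
    """A random genome with the requested GC content, split evenly into
    ``n_chromosomes`` named chr1..chrN. Deterministic in ``seed``."""
    if length < 0:
        raise ParameterError("length must be >= 0")
    if not 0.0 < gc < 1.0:
        raise ParameterError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    chroms = []
    if length == 0:
        return GenomeSequence(genome_id=genome_id, chromosomes=[])
    per = [length // n_chromosomes] * n_chromosomes
    per[-1] += length - sum(per)
    for i, clen in enumerate(per, 1):
        draws = rng.choice(4, size=clen, p=p)
        chroms.append((f"chr{i}", _BASES[draws].tobytes().decode()))
    return GenomeSequence(genome_id=genome_id, chromosomes=chroms)


# -- gene planting ----------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    stop = _STOPS[rng.integers(len(_STOPS))]
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + stop


def plant_genes(genome: GenomeSequence, n_genes: int, exons_per_gene: int = 2,
                cds_len_range: tuple[int, int] = (300, 900), seed: int = 0,
                intron_len_range: tuple[int, int] = (60, 300),
                spacing: int = 200):
    """Write ``n_genes`` intact ORFs into the genome.

    Returns ``(genome_with_genes, gene_models)``. Each emitted CDS starts
    with ATG, ends with a single stop, contains no internal in-frame stop
    and has length divisible by three; genes do not overlap. Raises
    :class:`PlacementError` when the genome cannot host the request.
    """
    if n_genes == 0:
        return genome, []
    rng = np.random.default_rng(seed)
    chrom_seqs = {name: bytearray(seq.encode()) for name, seq in genome.chromosomes}
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in chrom_seqs}
    names = [name for name, _ in genome.chromosomes]
    weights = np.array([len(chrom_seqs[n]) for n in names], dtype=float)
    if weights.sum() == 0:
        raise PlacementError("cannot plant genes into an empty genome")
    weights /= weights.sum()
    genes: list[GeneModel] = []
    for g in range(n_genes):
        n_codons = int(rng.integers(cds_len_range[0] // 3, cds_len_range[1] // 3 + 1))
        coding = _random_cds(rng, n_codons)
        n_exons = max(1, exons_per_gene)
        # split CDS into exon pieces of >= 3 bp
        cuts = sorted(
            rng.choice(np.arange(3, len(coding) - 2, 3), size=n_exons - 1,
                       replace=False)
        ) if n_exons > 1 else []
        pieces = []
        last = 0
        for cut in cuts:
            pieces.append(coding[last:cut])
            last = cut
        pieces.append(coding[last:])
        introns = [
            "".join(
                "ACGT"[i]
                for i in rng.integers(0, 4, size=int(rng.integers(*intron_len_range)))
            )
            for _ in range(n_exons - 1)
        ]
        region_plus = "".join(
            p + (introns[i] if i < len(introns) else "")
            for i, p in enumerate(pieces)
        )
        region_len = len(region_plus)
        strand = "+" if rng.random() < 0.5 else "-"
        placed = False
        for _attempt in range(1000):
            chrom = names[rng.choice(len(names), p=weights)]
            limit = len(chrom_seqs[chrom]) - region_len
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            if any(start - spacing < e and s < start + region_len + spacing
                   for s, e in occupied[chrom]):
                continue
            genomic = region_plus if strand == "+" else revcomp(region_plus)
            chrom_seqs[chrom][start : start + region_len] = genomic.encode()
            occupied[chrom].append((start, start + region_len))
            # exon coordinates from translation-order piece offsets
            cds_ivs = []
            off = 0
            for i, p in enumerate(pieces):
                if strand == "+":
                    cds_ivs.append(Interval(chrom, start + off, start + off + len(p)))
                else:
                    cds_ivs.append(
                        Interval(chrom, start + region_len - off - len(p),
                                 start + region_len - off)
                    )
                off += len(p) + (len(introns[i]) if i < len(introns) else 0)
            genes.append(
                GeneModel(gene_id=f"{genome.genome_id}_g{g + 1:04d}", chrom=chrom,
                          strand=strand, exons=list(cds_ivs), cds=cds_ivs)
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place gene {g + 1}/{n_genes} without overlap"
            )
    new_genome = GenomeSequence(
        genome_id=genome.genome_id,
        chromosomes=[(name, chrom_seqs[name].decode()) for name, _ in
                     genome.chromosomes],
    )
    return new_genome, sorted(genes, key=lambda g: (g.chrom, g.span.start))


# -- evolution --------------------------------------------------------------

class _Occupancy:
    """Per-chromosome boolean occupancy with a spacing buffer."""

    def __init__(self, lengths: dict[str, int], buffer: int):
        self.mask = {c: np.zeros(n, dtype=bool) for c, n in lengths.items()}
        self.buffer = buffer

    def block(self, chrom: str, start: int, end: int):
        lo = max(0, start - self.buffer)
        hi = min(len(self.mask[chrom]), end + self.buffer)
        self.mask[chrom][lo:hi] = True

    def free(self, chrom: str, start: int, end: int) -> bool:
        if start < 0 or end > len(self.mask[chrom]):
            return False
        return not self.mask[chrom][start:end].any()


def _place_span(rng, occ: _Occupancy, chrom_lengths, span: int,
                retries: int = 1000):
    names = list(chrom_lengths)
    weights = np.array([chrom_lengths[n] for n in names], dtype=float)
    weights /= weights.sum()
    for _ in range(retries):
        chrom = names[rng.choice(len(names), p=weights)]
        limit = chrom_lengths[chrom] - span
        if limit <= 0:
            continue
        start = int(rng.integers(0, limit))
        if occ.free(chrom, start, start + span):
            occ.block(chrom, start, start + span)
            return chrom, start
    raise SimulationError(
        f"event collision: no free {span} bp span after {retries} retries"
    )


def _random_seq(rng, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def evolve(ancestor: GenomeSequence, params: EvolutionParams,
           genome_id: str | None = None,
           protected: list[Interval] | None = None,
           genes: list[GeneModel] | None = None):
    """Derive one descendant; returns ``(derived, truth)``.

    ``protected`` intervals receive no events at all (used to keep reference
    gene models intact on the pivot branch). With ``params.purifying`` and
    ``genes`` given, indels landing in coding sequence are constrained to
    lengths divisible by three and to full containment in one CDS piece.
    """
    if ancestor.total_length == 0:
        raise ParameterError("cannot evolve an empty ancestor")
    rng = np.random.default_rng(params.seed)
    gid = genome_id or f"{ancestor.genome_id}_derived"
    lengths = ancestor.chrom_lengths
    occ = _Occupancy(lengths, params.min_event_spacing)
    for iv in protected or []:
        occ.block(iv.chrom, iv.start, iv.end)
    cds_mask = {c: np.zeros(n, dtype=bool) for c, n in lengths.items()}
    cds_pieces: list[Interval] = []
    for gene in genes or []:
        for iv in gene.cds:
            cds_mask[iv.chrom][iv.start : iv.end] = True
            cds_pieces.append(iv)
    events: list[Event] = []

    # large events first: CNV, then PAV
    for _ in range(params.cnv_count):
        span = int(rng.integers(params.cnv_len[0], params.cnv_len[1] + 1))
        copies = rng.choice(
            list(params.cnv_copy_weights),
            p=np.array(list(params.cnv_copy_weights.values()))
            / sum(params.cnv_copy_weights.values()),
        )
        chrom, start = _place_span(rng, occ, lengths, span)
        if copies == 0:
            events.append(Event("cnv_loss", chrom, start, start + span))
        else:
            events.append(
                Event("cnv_gain", chrom, start, start + span, copies=int(copies))
            )
    n_gain = int(round(params.pav_count * params.pav_gain_frac))
    for i in range(params.pav_count):
        span = int(rng.integers(params.pav_len[0], params.pav_len[1] + 1))
        if i < n_gain:
            chrom, start = _place_span(rng, occ, lengths, 1)
            events.append(
                Event("pav_gain", chrom, start, start, seq=_random_seq(rng, span))
            )
        else:
            chrom, start = _place_span(rng, occ, lengths, span)
            events.append(Event("pav_loss", chrom, start, start + span))

    # small indels
    n_indels = rng.binomial(ancestor.total_length, params.indel_rate)
    chrom_names_all = list(lengths)
    chrom_w = np.array([lengths[c] for c in chrom_names_all], dtype=float)
    chrom_w /= chrom_w.sum()
    for _ in range(n_indels):
        size = min(int(rng.geometric(params.indel_geom_p)), params.indel_max)
        is_ins = rng.random() < 0.5
        for _attempt in range(1000):
            chrom = chrom_names_all[rng.choice(len(chrom_names_all), p=chrom_w)]
            limit = lengths[chrom] - params.indel_max
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            size_eff = size
            if params.purifying:
                # judge the whole event footprint with a guard band of the
                # maximum left-alignment shift, so boundary-straddling (or
                # boundary-shiftable) indels can never leak a frameshift
                guard = params.indel_max
                lo = max(0, start - guard)
                hi = start + (1 if is_ins else size) + guard
                if cds_mask[chrom][lo:hi].any():
                    size_eff = int(rng.choice([3, 6, 9]))
                    piece = next(
                        (iv for iv in cds_pieces
                         if iv.chrom == chrom
                         and iv.start + guard <= start
                         and start + (1 if is_ins else size_eff) + guard
                         <= iv.end),
                        None,
                    )
                    if piece is None:
                        continue  # near a CDS boundary; try elsewhere
            span = 1 if is_ins else size_eff
            if not occ.free(chrom, start, start + span):
                continue
            occ.block(chrom, start, start + span)
            if is_ins:
                events.append(
                    Event("ins", chrom, start, start,
                          seq=_random_seq(rng, size_eff))
                )
            else:
                ref = ancestor.seq(chrom)[start : start + size_eff]
                events.append(Event("del", chrom, start, start + size_eff, ref=ref))
            break
        else:
            raise SimulationError("indel placement failed after 1000 retries")
    # SNPs fill remaining free positions
    n_snps = rng.binomial(ancestor.total_length, params.snp_rate)
    free_by_chrom = {c: np.flatnonzero(~occ.mask[c]) for c in lengths}
    all_free = sum(len(v) for v in free_by_chrom.values())
    if n_snps > all_free:
        raise SimulationError("not enough free positions for requested SNPs")
    chrom_names = list(lengths)
    chrom_p = np.array([len(free_by_chrom[c]) for c in chrom_names], dtype=float)
    chrom_p /= chrom_p.sum()
    per_chrom = rng.multinomial(n_snps, chrom_p)
    for c, count in zip(chrom_names, per_chrom):
        count = min(count, len(free_by_chrom[c]))
        positions = rng.choice(free_by_chrom[c], size=count, replace=False)
        seq = ancestor.seq(c)
        for pos in sorted(int(p) for p in positions):
            ref = seq[pos]
            if ref == "N":
                continue
            alt = "ACGT"[int(rng.integers(0, 3))]
            if alt == ref:
                alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            events.append(Event("snp", c, pos, pos + 1, seq=alt, ref=ref))

    truth = TruthSet(genome_id=gid, events=sorted(
        events, key=lambda e: (e.chrom, e.donor_start, e.donor_end)
    ))
    derived = truth.replay(ancestor)
    # fill recipient coordinates
    for e in truth.events:
        e.recipient_start = truth.lift(e.chrom, e.donor_start)
        if e.etype == "snp":
            e.recipient_end = e.recipient_start + 1
        elif e.etype in ("ins", "pav_gain"):
            e.recipient_end = e.recipient_start + len(e.seq)
        elif e.etype == "cnv_gain":
            e.recipient_end = e.recipient_start + e.copies * e.donor_span
        else:
            e.recipient_end = e.recipient_start
    expected = ancestor.total_length + sum(e.length_delta() for e in truth.events)
    if derived.total_length != expected:
        raise SimulationError("length bookkeeping failed after replay")
    return derived, truth


# -- gene lifting -----------------------------------------------------------

def lift_genes(genes: list[GeneModel], truth: TruthSet) -> list[GeneModel]:
    """Map gene models through a branch's events into derived coordinates.

    Genes whose span intersects a segmental deletion are dropped (absent in
    the derived genome); all other boundaries are shifted through the offset
    map. Lifted genes are positional annotations only: their ORFs may carry
    the branch's point mutations.
    """
    deleted = truth.deleted_intervals()
    out = []
    for gene in genes:
        span = gene.span
        if any(span.overlaps(d) for d in deleted):
            continue
        try:
            exons = [
                Interval(gene.chrom, truth.lift(gene.chrom, iv.start),
                         truth.lift(gene.chrom, iv.end))
                for iv in gene.exons
            ]
            cds = [
                Interval(gene.chrom, truth.lift(gene.chrom, iv.start),
                         truth.lift(gene.chrom, iv.end))
                for iv in gene.cds
            ]
            out.append(replace(gene, exons=exons, cds=cds))
        except Exception:
            continue  # degenerate after lifting (fully inside an event)
    return out


# -- depth tracks -----------------------------------------------------------

@dataclass
class DepthTrack:
    """Windowed mean fold-coverage on one genome's coordinates."""

    genome_id: str
    windows: list[tuple[Interval, float]]


def simulate_depth(genome: GenomeSequence, truth: TruthSet, mean_depth: float,
                   window: int = 100, noise: str = "poisson",
                   overdispersion: float | None = None,
                   seed: int = 0) -> DepthTrack:
    """Read-depth track of the derived sample on the donor genome's
    coordinates: window depth is centred at ``mean_depth x copy_number``
    with copy numbers taken from the truth set's CNV events (0 for losses,
    2-3 for gains, 1 elsewhere).

    noise: ``"none"`` (exact), ``"poisson"`` (default) or ``"nb"``
    (negative binomial with the given overdispersion r).
    """
    if mean_depth <= 0:
        raise ParameterError("mean_depth must be > 0")
    if window < 100:
        raise ParameterError("window must be >= 100 bp")
    rng = np.random.default_rng(seed)
    windows: list[tuple[Interval, float]] = []
    for chrom, length in genome.chrom_lengths.items():
        copy = np.ones(length, dtype=float)
        for e in truth.by_type("cnv_gain"):
            if e.chrom == chrom:
                copy[e.donor_start : e.donor_end] = e.copies
        for e in truth.by_type("cnv_loss"):
            if e.chrom == chrom:
                copy[e.donor_start : e.donor_end] = 0.0
        for start in range(0, length, window):
            end = min(start + window, length)
            center = mean_depth * float(copy[start:end].mean())
            if noise == "none":
                depth = center
            elif noise == "poisson":
                depth = float(rng.poisson(center))
            elif noise == "nb":
                r = overdispersion or 10.0
                p = r / (r + center) if center > 0 else 1.0
                depth = float(rng.negative_binomial(r, p)) if center > 0 else 0.0
            else:
                raise ParameterError(f"unknown noise model {noise!r}")
            windows.append((Interval(chrom, start, end), depth))
    return DepthTrack(genome_id=truth.genome_id, windows=windows)


def write_truth_tsv(truth: TruthSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("genome\ttype\tchrom\tdonor_start\tdonor_end\t"
                 "recipient_start\trecipient_end\tcopies\tref\tseq\n")
        for e in truth.events:
            fh.write(
                f"{truth.genome_id}\t{e.etype}\t{e.chrom}\t{e.donor_start}\t"
                f"{e.donor_end}\t{e.recipient_start}\t{e.recipient_end}\t"
                f"{e.copies}\t{e.ref}\t{e.seq}\n"
            )
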