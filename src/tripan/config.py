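"""Threshold configuration shared by every pipeline stage.

The defaults are the working thresholds of the tri-genome comparison:
PAV segments are called at > 100 bp and <= 95% best-realignment identity and
merged across < 500 bp gaps; CNV regions need >= 500 bp and a windowed depth
ratio outside [cnv_low, cnv_high]; variants <= 10 bp are "small", larger ones
enter the six-category structural classifier, whose repeat-vs-plain-indel
decision uses ``repeat_gap_min``.

Note on CNV ratios: a published rule of "depth < 1.2 or > 1.8 of the mean"
would flag every normal-depth (1.0x) window as a loss; the shipped defaults
are the sane symmetric pair 0.5/1.5, with the verbatim printed pair available
through :meth:`ThresholdConfig.printed_cnv_thresholds` for anyone who wants
to reproduce that behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import ParameterError


@dataclass(frozen=True)
class ThresholdConfig:
    # Presence-absence variation
    pav_min_len: int = 100          # bp; records must be strictly longer
    pav_max_identity: float = 0.95  # best realignment identity allowed for a PAV
    pav_merge_gap: int = 500        # merge uncovered blocks separated by < this
    pav_gene_cds_frac: float = 0.5  # CDS fraction for absence gene calls
    pav_specific_gene_cds_frac: float = 0.8  # CDS fraction for specific-gene calls
    # Copy-number variation
    cnv_min_len: int = 500          # bp; minimum CNV region length
    cnv_low: float = 0.5            # normalized depth below -> loss
    cnv_high: float = 1.5           # normalized depth above -> gain
    cnv_gene_exon_frac: float = 0.8  # exon fraction for CNV gene calls
    # Variant size classes
    large_variant_min: int = 10     # bp; >= enters the structural classifier
    small_variant_max: int = 10     # bp; <= is a small indel
    repeat_gap_min: int = 50        # bp; min(dr, dq) above this -> repeat class
    # Anchoring / chaining
    anchor_k: int = 21              # k-mer size (odd, 11..31)
    min_chain_len: int = 100        # bp anchored; shorter chains are dropped
    max_bridge: int = 10_000        # bp; larger interstices split chains
    max_anchor_occ: int = 1         # per-genome k-mer occurrence cap ("sv" mode: 3)
    # Gene presence in the pan-genome
    gene_presence_frac: float = 0.8  # CDS fraction aligned -> gene "present"

    def __post_init__(self):
        for name in (
            "pav_min_len", "pav_merge_gap", "cnv_min_len",
            "large_variant_min", "small_variant_max", "repeat_gap_min",
            "anchor_k", "min_chain_len", "max_bridge", "max_anchor_occ",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        for name in (
            "pav_max_identity", "pav_gene_cds_frac",
            "pav_specific_gene_cds_frac", "cnv_gene_exon_frac",
            "gene_presence_frac",
        ):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ParameterError(f"{name} must be in (0, 1], got {value}")
        if not 0 < self.cnv_low < self.cnv_high:
            raise ParameterError("require 0 < cnv_low < cnv_high")
        if self.anchor_k % 2 == 0 or not 11 <= self.anchor_k <= 31:
            raise ParameterError("anchor_k must be odd and in [11, 31]")

    def printed_cnv_thresholds(self) -> "ThresholdConfig":
        """The verbatim published depth-ratio pair (1.2 / 1.8).

        Kept available but not default: with these bounds every unchanged
        window (ratio ~1.0 < 1.2) is a loss candidate.
        """
        return replace(self, cnv_low=1.2, cnv_high=1.8)

    def sv_mode(self) -> "ThresholdConfig":
        """Alignment settings for structural-variant discovery.

        Allows k-mers seen up to 3x per genome so duplicated units anchor each
        copy, which is what makes tandem expansions/contractions visible as
        overlapping blocks.
        """
        return replace(self, max_anchor_occ=3)


DEFAULT_CONFIG = ThresholdConfig()
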