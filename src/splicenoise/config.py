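"""Configuration objects for the simulator and the analysis pipeline.

``SimConfig`` holds the generative assumptions of the synthetic dataset:
gene architecture, the per-intron cryptic-splicing probability, the
frame-biased survival of error isoforms (a proxy for nonsense-mediated
decay), and sequencing parameters.  ``RunConfig`` collects every analysis
threshold so a run report can echo them all.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass
class SimConfig:
    """Parameters of the synthetic genome / transcriptome / read generator.

    Defaults describe a small but realistic vertebrate-like locus set:
    multi-exon genes (geometric exon count, mean 4), log-normal intron
    lengths within the mapper's discoverable range (60–20,000 bp),
    power-law expression, and a per-intron splicing error rate of 0.7%.
    """

    n_genes: int = 100
    # exon count ~ 1 + Geometric(p); p = 1/(mean_exons - 1) gives the target mean
    mean_exons: int = 4
    min_exons: int = 2
    max_exons: int = 12
    exon_length_min: int = 50
    exon_length_max: int = 300
    # intron length ~ exp(Normal(mu, sigma)) clipped to [min, max]
    intron_log_mean: float = 5.9  # median ≈ 365 bp
    intron_log_sigma: float = 0.9
    intron_length_min: int = 60
    intron_length_max: int = 20_000
    intergenic_min: int = 300
    intergenic_max: int = 800
    # fraction of donors using the minor GC dinucleotide (GC-AG introns)
    gc_donor_fraction: float = 0.03
    minus_strand_fraction: float = 0.5
    # expression weights ~ 1 + Pareto(alpha); optionally coupled to intron length
    expression_alpha: float = 1.2
    # >0 makes highly expressed genes have shorter introns (confounding)
    expression_length_coupling: float = 0.0
    # per-intron cryptic splicing probability: eps(L) = error_rate + error_length_slope * log10(L)
    per_intron_error_rate: float = 0.007
    error_length_slope: float = 0.0
    # survival multiplier for frame-disrupting error isoforms (NMD proxy)
    frame_bias: float = 1.0
    # cryptic-site proposal kernel: geometric decay with distance from true site
    cryptic_decay: float = 0.97
    cryptic_exon_flank: int = 30
    cryptic_max_offset: int = 98
    cryptic_min_offset: int = 3  # offsets in -2..+2 are ambiguous / identical
    # sequencing
    read_length: int = 46
    sequencing_error_rate: float = 0.001
    depth: float = 50.0  # mean junction-spanning reads per true junction
    # conservation track
    conserved_mean: float = 2.0
    conserved_sd: float = 0.3
    background_mean: float = 0.05
    background_sd: float = 0.15
    # polymorphism
    variant_rate: float = 0.001
    # artifact chimeric reads (mapping-noise model for FDR calibration)
    n_artifact_reads: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        # per_intron_error_rate may be negative as an intercept when a
        # length slope is set; the realized eps(L) is clipped to [0, 0.5]
        for name in ("gc_donor_fraction", "minus_strand_fraction",
                     "frame_bias", "sequencing_error_rate", "variant_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.error_length_slope == 0.0 and not 0.0 <= self.per_intron_error_rate <= 1.0:
            raise ValueError("per_intron_error_rate must be in [0, 1]")
        if self.intron_length_min < 60 or self.intron_length_max > 20_000:
            raise ValueError("intron lengths must stay within [60, 20000] "
                             "so every true junction is discoverable")
        if self.exon_length_min < 40:
            raise ValueError("exons shorter than 40 bp break read-context assembly")
        if self.read_length < 20:
            raise ValueError("read_length must be >= seed length (20)")
        if not 0 < self.cryptic_decay < 1:
            raise ValueError("cryptic_decay must be in (0, 1)")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        return cls(**json.loads(text))


@dataclass
class RunConfig:
    """Analysis thresholds and paths for a pipeline run.

    Every threshold is echoed in the run report; defaults follow the
    conventions of the junction catalogue and noise analyses (canonical
    seed length 20, minimum overhang 10, intron span 51–20,000 bp).
    """

    seed_length: int = 20
    min_overhang: int = 10
    min_intron: int = 51
    max_intron: int = 20_000
    max_mismatches: int = 2
    discard_short_both_end: bool = True  # reads <40 bp with both ends mapped
    conserved_threshold: float = 1.5  # T_hi on the two canonical bases
    unconserved_threshold: float = 0.5
    usage_min_coverage: int = 50
    periodicity_min_coverage: int = 20
    periodicity_major_share: float = 0.90
    periodicity_window: int = 101
    near_annotated_bp: int = 50
    motif_window: int = 50  # bases on each side of a site before exclusions
    motif_alpha: float = 0.05
    n_bins: int = 100
    outdir: Path | None = None
    seed: int = 0

    def asdict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["outdir"] is not None:
            d["outdir"] = str(d["outdir"])
        return d


def derive_seed(seed: int, stage: str) -> int:
    """Fan a single run seed out to per-stage seeds, reproducibly."""
    import zlib

    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)
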