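"""One-call assembly of a complete synthetic dataset."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..config import SimConfig, derive_seed
from .conservation import ConservationTrack, generate_conservation_track
from .genome import Genome, generate_genome
from .transcripts import build_truth
from .truth import TruthSet
from .variants import generate_variant_positions


@dataclass
class SimData:
    """Bundle of simulator outputs consumed by the analyses."""

    config: SimConfig
    genome: Genome
    truth: TruthSet
    track: ConservationTrack
    variant_positions: dict[str, np.ndarray]


def simulate_dataset(config: SimConfig, seed: int | None = None) -> SimData:
    """Generate genome, truth, conservation track, and polymorphism set.

    The single seed fans out to per-stage seeds so each stage is
    individually reproducible.
    """
    seed = config.seed if seed is None else seed
    genome, genes, introns = generate_genome(config, derive_seed(seed, "genome"))
    rng = np.random.default_rng(derive_seed(seed, "truth"))
    truth = build_truth(genome, genes, introns, config, rng)
    track = generate_conservation_track(genome, truth, config,
                                        derive_seed(seed, "conservation"))
    positions = generate_variant_positions(genome, truth, config,
                                           derive_seed(seed, "variants"))
    return SimData(config=config, genome=genome, truth=truth, track=track,
                   variant_positions=positions)
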