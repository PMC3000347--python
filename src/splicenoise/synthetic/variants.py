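"""Synthetic polymorphism positions.

Variants fall uniformly at a per-base rate, except at the canonical
dinucleotides of true splice sites, which are kept monomorphic — real
populations show reduced polymorphism directly intronic of functional
splice sites, and this is the feature the polymorphism profile detects.
Cryptic (error) splice sites receive no such protection.
"""

from __future__ import annotations

import numpy as np

from ..config import SimConfig
from .genome import Genome
from .truth import TruthSet


def generate_variant_positions(genome: Genome, truth: TruthSet,
                               config: SimConfig, seed: int) -> dict[str, np.ndarray]:
    """Sorted variant positions per chromosome."""
    rng = np.random.default_rng(seed)
    protected: dict[str, set[int]] = {c: set() for c in genome.chrom_names}
    for g in truth.genes:
        for s, e in g.introns:
            protected[g.chrom].update((s, s + 1, e - 2, e - 1))
    out = {}
    for chrom in genome.chrom_names:
        n = genome.length(chrom)
        pos = np.nonzero(rng.random(n) < config.variant_rate)[0]
        if protected[chrom]:
            keep = ~np.isin(pos, np.fromiter(protected[chrom], dtype=np.int64))
            pos = pos[keep]
        out[chrom] = pos
    return out


def write_variant_bed(positions: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for chrom, pos in positions.items():
            for p in pos:
                fh.write(f"{chrom}\t{p}\t{p + 1}\n")


def read_variant_bed(path) -> dict[str, np.ndarray]:
    acc: dict[str, list[int]] = {}
    with open(path) as fh:
        for line in fh:
            chrom, s, _ = line.split()[:3]
            acc.setdefault(chrom, []).append(int(s))
    return {c: np.array(sorted(v), dtype=np.int64) for c, v in acc.items()}
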