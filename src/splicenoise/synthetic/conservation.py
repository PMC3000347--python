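"""Per-base conservation track emulation.

Real conservation scores (e.g. phyloP) are high at functional splice
sites and exons and near zero in neutral sequence.  The generated track
draws exonic bases and true splice-site dinucleotides from a "conserved"
normal distribution and everything else — including the dinucleotides of
every cryptic splice candidate, even those falling inside exons — from a
near-zero background, so that simulator-designated error sites are
unconserved by construction.
"""

from __future__ import annotations

import numpy as np

from ..config import SimConfig
from .genome import Genome
from .truth import TruthSet


class ConservationTrack:
    """Per-base scores addressable by (chromosome, position)."""

    def __init__(self, scores: dict[str, np.ndarray]):
        self._scores = {c: np.asarray(a, dtype=np.float32) for c, a in scores.items()}

    def score(self, chrom: str, pos: int) -> float:
        return float(self._scores[chrom][pos])

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        return self._scores[chrom][max(start, 0):end]

    def mean(self, chrom: str, positions) -> float:
        return float(self._scores[chrom][np.asarray(positions)].mean())

    def array(self, chrom: str) -> np.ndarray:
        return self._scores[chrom]

    def covers(self, chrom: str, start: int, end: int) -> bool:
        return chrom in self._scores and start >= 0 and end <= len(self._scores[chrom])

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, arr in self._scores.items():
                # run-length encode equal adjacent values
                vals = np.round(arr, 4)
                change = np.nonzero(np.diff(vals))[0] + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [len(vals)]])
                for s, e in zip(starts, ends):
                    fh.write(f"{chrom}\t{s}\t{e}\t{vals[s]:.4f}\n")

    @classmethod
    def from_bedgraph(cls, path, lengths: dict[str, int]) -> "ConservationTrack":
        scores = {c: np.zeros(n, dtype=np.float32) for c, n in lengths.items()}
        with open(path) as fh:
            for line in fh:
                chrom, s, e, v = line.split()
                scores[chrom][int(s):int(e)] = float(v)
        return cls(scores)


def _site_dinuc_positions(truth: TruthSet) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """Forward-genome positions of (true, cryptic) splice-site dinucleotides."""
    true_pos, cryptic_pos = [], []
    for g in truth.genes:
        for s, e in g.introns:
            true_pos += [(g.chrom, s), (g.chrom, s + 1), (g.chrom, e - 2), (g.chrom, e - 1)]
    for (gid, ii), cands in truth.variants.items():
        gene = truth.gene_by_id[gid]
        s, e = gene.introns[ii]
        for v in cands:
            # the moved boundary carries the cryptic dinucleotide
            if (v.start, v.end) == (s, e):
                continue
            if v.start != s:
                cryptic_pos += [(gene.chrom, v.start), (gene.chrom, v.start + 1)]
            if v.end != e:
                cryptic_pos += [(gene.chrom, v.end - 2), (gene.chrom, v.end - 1)]
    return true_pos, cryptic_pos


def generate_conservation_track(genome: Genome, truth: TruthSet,
                                config: SimConfig, seed: int) -> ConservationTrack:
    """Emulated conservation: exons and true splice sites high, rest background."""
    rng = np.random.default_rng(seed)
    scores = {}
    for chrom, seq in genome.items():
        scores[chrom] = rng.normal(config.background_mean, config.background_sd,
                                   size=len(seq)).astype(np.float32)
    for g in truth.genes:
        for s, e in g.exons:
            scores[g.chrom][s:e] = rng.normal(config.conserved_mean, config.conserved_sd,
                                              size=e - s)
    true_pos, cryptic_pos = _site_dinuc_positions(truth)
    for chrom, p in true_pos:
        scores[chrom][p] = rng.normal(config.conserved_mean, config.conserved_sd)
    for chrom, p in cryptic_pos:
        scores[chrom][p] = rng.normal(config.background_mean, config.background_sd)
    return ConservationTrack(scores)
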