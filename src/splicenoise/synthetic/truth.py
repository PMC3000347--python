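"""Ground-truth containers for the simulator.

All coordinates are 0-based, half-open, on the forward strand of the
synthetic genome.  A junction is keyed by its intron interval
``(chrom, strand, start, end)``: the intron occupies ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

JunctionKey = tuple[str, str, int, int]


def junction_key(chrom: str, strand: str, start: int, end: int) -> JunctionKey:
    return (chrom, strand, int(start), int(end))


@dataclass(frozen=True)
class GeneModel:
    """A gene: ordered genomic exon intervals plus a strand.

    ``exons`` are forward-genome intervals sorted by coordinate; for a
    minus-strand gene transcription runs right to left, so the genomic
    last exon is the transcriptional first.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(self.exons[i][1], self.exons[i + 1][0])
                for i in range(len(self.exons) - 1)]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def intron_keys(self) -> list[JunctionKey]:
        return [junction_key(self.chrom, self.strand, s, e)
                for s, e in self.introns]


@dataclass(frozen=True)
class Variant:
    """A cryptic splice choice for one intron.

    ``offset`` is the signed distance from the true site in transcription
    direction (positive = downstream, i.e. into the intron for donors and
    into the exon for acceptors).  ``start``/``end`` give the resulting
    intron interval on the forward genome; ``in_frame`` is true when the
    offset is a multiple of three (the downstream reading frame survives).
    """

    side: str  # 'D' donor (5' splice site) or 'A' acceptor (3')
    offset: int
    start: int
    end: int
    in_frame: bool
    weight: float


@dataclass
class TruthSet:
    """The simulator's record of what was generated.

    ``introns`` has one row per true intron with its per-intron error
    probability; ``variants`` lists the cryptic candidates available to
    each intron (the proposal support of the error kernel);
    ``error_junctions`` maps junction keys actually used by simulated
    error events back to their generating intron and offset.
    """

    genes: list[GeneModel]
    introns: pd.DataFrame
    expression: dict[str, float]
    variants: dict[tuple[str, int], list[Variant]]
    true_junctions: set[JunctionKey] = field(default_factory=set)
    error_junctions: dict[JunctionKey, tuple[str, int, str, int]] = field(default_factory=dict)
    isoform_labels: pd.DataFrame | None = None
    retained_introns: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.true_junctions:
            self.true_junctions = {k for g in self.genes for k in g.intron_keys()}

    @property
    def gene_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def record_error_junction(self, key: JunctionKey, gene_id: str,
                              intron_idx: int, side: str, offset: int) -> None:
        if key in self.true_junctions:
            raise ValueError(f"error junction {key} collides with a true junction")
        self.error_junctions.setdefault(key, (gene_id, intron_idx, side, offset))

    def check_invariants(self) -> None:
        if set(self.error_junctions) & self.true_junctions:
            raise AssertionError("true and error junction sets overlap")
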