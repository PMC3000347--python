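"""Synthetic genome and gene-model generation.

Genes are laid out left to right on a single synthetic chromosome with
random intergenic gaps; architecture is drawn per gene (geometric exon
count, uniform exon lengths, clipped log-normal intron lengths) and the
sequence is uniform random DNA with canonical splice dinucleotides forced
at every intron boundary: GT (or GC at a small configurable fraction) at
the donor and AG at the acceptor, in transcription orientation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .._seq import random_dna, revcomp, seq_to_array
from ..config import SimConfig
from .truth import GeneModel

MAX_GENOME_LENGTH = 100_000_000


class Genome:
    """In-memory genome: chromosome name -> uppercase ACGT string."""

    def __init__(self, chroms: dict[str, str]):
        self._chroms = dict(chroms)
        self._arrays: dict[str, np.ndarray] = {}

    @property
    def chrom_names(self) -> list[str]:
        return list(self._chroms)

    def seq(self, chrom: str) -> str:
        return self._chroms[chrom]

    def array(self, chrom: str) -> np.ndarray:
        if chrom not in self._arrays:
            self._arrays[chrom] = seq_to_array(self._chroms[chrom])
        return self._arrays[chrom]

    def length(self, chrom: str) -> int:
        return len(self._chroms[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self._chroms[chrom][max(start, 0):end]

    def fetch_sense(self, chrom: str, start: int, end: int, strand: str) -> str:
        s = self.fetch(chrom, start, end)
        return s if strand == "+" else revcomp(s)

    def items(self):
        return self._chroms.items()

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, rebuild=True)
        return cls({name: str(fa[name][:]).upper() for name in fa.keys()})


def _draw_exon_count(rng: np.random.Generator, cfg: SimConfig) -> int:
    # 1 + Geometric(p) has mean 1 + 1/p; p chosen so the mean is mean_exons
    p = 1.0 / max(cfg.mean_exons - 1, 1)
    n = 1 + rng.geometric(p)
    return int(min(max(n, cfg.min_exons), cfg.max_exons))


def _draw_intron_length(rng: np.random.Generator, cfg: SimConfig) -> int:
    L = int(round(np.exp(rng.normal(cfg.intron_log_mean, cfg.intron_log_sigma))))
    return int(min(max(L, cfg.intron_length_min), cfg.intron_length_max))


def generate_genome(config: SimConfig, seed: int | None = None
                    ) -> tuple[Genome, list[GeneModel], pd.DataFrame]:
    """Generate a genome and gene models.

    Returns ``(genome, genes, introns)`` where ``introns`` is a table with
    one row per true intron (gene, index, coordinates, length, donor
    dinucleotide class).  Deterministic for a fixed ``(config, seed)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    chrom = "chr1"

    genes: list[GeneModel] = []
    intron_rows: list[dict] = []
    cursor = int(rng.integers(config.intergenic_min, config.intergenic_max + 1))
    for gi in range(config.n_genes):
        gene_id = f"g{gi:04d}"
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        n_exons = _draw_exon_count(rng, config)
        exon_lens = rng.integers(config.exon_length_min, config.exon_length_max + 1,
                                 size=n_exons)
        intron_lens = [_draw_intron_length(rng, config) for _ in range(n_exons - 1)]
        exons = []
        pos = cursor
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if i < n_exons - 1:
                pos += intron_lens[i]
        cursor = pos + int(rng.integers(config.intergenic_min, config.intergenic_max + 1))
        gene = GeneModel(gene_id, chrom, strand, tuple(exons))
        genes.append(gene)
        for ii, (s, e) in enumerate(gene.introns):
            donor_class = "GC" if rng.random() < config.gc_donor_fraction else "GT"
            intron_rows.append(dict(gene_id=gene_id, intron_idx=ii, chrom=chrom,
                                    strand=strand, start=s, end=e, length=e - s,
                                    donor_class=donor_class))

    total = cursor
    if total > MAX_GENOME_LENGTH:
        raise ValueError(f"generated genome length {total} exceeds "
                         f"{MAX_GENOME_LENGTH}; reduce n_genes or intron lengths")

    arr = random_dna(total, rng)
    seq = bytearray(arr.tobytes())
    for row in intron_rows:
        s, e = row["start"], row["end"]
        donor = row["donor_class"]
        if row["strand"] == "+":
            seq[s:s + 2] = donor.encode()
            seq[e - 2:e] = b"AG"
        else:
            # sense donor at the genomic right end, acceptor at the left
            seq[e - 2:e] = revcomp(donor).encode()
            seq[s:s + 2] = b"CT"

    genome = Genome({chrom: seq.decode("ascii")})
    introns = pd.DataFrame(intron_rows)
    return genome, genes, introns
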