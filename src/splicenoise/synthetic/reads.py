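"""Short-read simulation.

Two generators are provided: :func:`simulate_reads` samples read starts
uniformly along isoform sequences (abundance-weighted), which mirrors a
whole-transcript sequencing experiment at small scale;
:func:`simulate_junction_reads` emits junction-spanning reads only, with
per-junction counts from the error model and the breakpoint uniform
within the read — the efficient route to deep junction coverage.  Read
ids encode the source isoform and breakpoint for truth tracing.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .._seq import array_to_seq, encode_2bit, seq_to_array
from ..config import SimConfig
from .genome import Genome
from .transcripts import isoform_sequence, simulate_junction_counts
from .truth import GeneModel, TruthSet, Variant


class ReadRecord(NamedTuple):
    read_id: str
    seq: str


def parse_read_id(read_id: str) -> dict:
    """Decode the truth fields embedded in a simulated read id."""
    fields = read_id.split("|")
    out = {"serial": fields[0]}
    for f in fields[1:]:
        k, _, v = f.partition("=")
        out[k] = v
    return out


def _apply_sequencing_errors(mat: np.ndarray, rate: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Substitute bases in an (n_reads, L) ASCII matrix at the given rate."""
    if rate <= 0 or mat.size == 0:
        return mat
    codes = encode_2bit(mat)
    mask = rng.random(mat.shape) < rate
    shift = rng.integers(1, 4, size=int(mask.sum()))
    codes[mask] = (codes[mask] + shift) % 4
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = mat.copy()
    out[mask] = lut[codes[mask]]
    return out


def _junction_tx_position(gene: GeneModel, exons: list[list[int]], intron_idx: int) -> int:
    """Transcript (sense) coordinate of the junction closing intron ``intron_idx``."""
    lens = [e - s for s, e in exons]
    if gene.strand == "+":
        return sum(lens[:intron_idx + 1])
    return sum(lens[intron_idx + 1:])


def _junction_context(genome: Genome, gene: GeneModel, intron_idx: int,
                      variant: Variant | None, flank: int
                      ) -> tuple[str, int]:
    """Sense sequence around a junction and the junction's offset within it."""
    vmap = {intron_idx: variant} if variant is not None else None
    exons = [list(x) for x in gene.exons]
    if variant is not None:
        exons[intron_idx][1] = variant.start
        exons[intron_idx + 1][0] = variant.end
    tx = isoform_sequence(genome, gene, vmap)
    pos = _junction_tx_position(gene, exons, intron_idx)
    left = min(flank, pos)
    right = min(flank, len(tx) - pos)
    return tx[pos - left:pos + right], left


def simulate_junction_reads(genome: Genome, truth: TruthSet, config: SimConfig,
                            seed: int, total_reads: int | None = None,
                            counts: pd.DataFrame | None = None,
                            return_matrix: bool = False):
    """Generate junction-spanning reads.

    Returns ``(reads, counts)`` where ``counts`` is the per-junction truth
    table the reads were drawn from.  Breakpoints are uniform over all
    spanning positions (at least one base on each side); reads whose
    context cannot accommodate the read length are dropped.
    """
    rng = np.random.default_rng(seed)
    if counts is None:
        counts = simulate_junction_counts(genome, truth, config,
                                          int(rng.integers(2**31)), total_reads)
    L = config.read_length
    gene_by_id = truth.gene_by_id
    variant_lookup = {
        (gid, ii, v.side, v.offset): v
        for (gid, ii), vs in truth.variants.items() for v in vs
    }
    mats, ids = [], []
    serial = 0
    for row in counts.itertuples(index=False):
        n = int(row.reads)
        gene = gene_by_id[row.gene_id]
        variant = None
        if row.is_error:
            variant = variant_lookup[(row.gene_id, int(row.intron_idx),
                                      row.side, int(row.offset))]
        ctx, jpos = _junction_context(genome, gene, int(row.intron_idx),
                                      variant, flank=L - 1)
        left_avail, right_avail = jpos, len(ctx) - jpos
        b_lo, b_hi = max(1, L - right_avail), min(L - 1, left_avail)
        if b_hi < b_lo:
            continue
        b = rng.integers(b_lo, b_hi + 1, size=n)
        ctx_arr = seq_to_array(ctx)
        windows = np.lib.stride_tricks.sliding_window_view(ctx_arr, L)
        mats.append(windows[jpos - b])
        tag = (f"g={row.gene_id}|i={row.intron_idx}|v={row.side}"
               f"{row.offset if row.side != 'T' else ''}")
        for bb in b:
            ids.append(f"sim{serial}|{tag}|b={bb}")
            serial += 1
    if not mats:
        return ([], counts) if not return_matrix else ([], np.empty((0, L), np.uint8), counts)
    mat = np.concatenate(mats, axis=0)
    mat = _apply_sequencing_errors(mat, config.sequencing_error_rate, rng)
    if return_matrix:
        return ids, mat, counts
    reads = [ReadRecord(rid, array_to_seq(mat[i])) for i, rid in enumerate(ids)]
    return reads, counts


def simulate_reads(genome: Genome, truth: TruthSet, config: SimConfig,
                   seed: int, n_reads: int = 10_000,
                   isoforms: pd.DataFrame | None = None) -> list[ReadRecord]:
    """Uniform-start reads along correctly spliced transcripts.

    Used for expression estimation and as contiguously mapping background;
    junction-focused studies use :func:`simulate_junction_reads`.
    Transcripts shorter than the read length are skipped.
    """
    rng = np.random.default_rng(seed)
    L = config.read_length
    genes = truth.genes
    txs = [isoform_sequence(genome, g) for g in genes]
    w = np.array([truth.expression[g.gene_id] * max(len(t) - L + 1, 0)
                  for g, t in zip(genes, txs)], dtype=float)
    if w.sum() == 0:
        return []
    alloc = rng.multinomial(n_reads, w / w.sum())
    reads: list[ReadRecord] = []
    serial = 0
    for gene, tx, n in zip(genes, txs, alloc):
        if n == 0:
            continue
        starts = rng.integers(0, len(tx) - L + 1, size=n)
        arr = seq_to_array(tx)
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)[starts]
        windows = _apply_sequencing_errors(windows, config.sequencing_error_rate, rng)
        for i, s in enumerate(starts):
            reads.append(ReadRecord(f"sim{serial}|g={gene.gene_id}|v=C|b={s}",
                                    array_to_seq(windows[i])))
            serial += 1
    return reads


def simulate_artifact_reads(genome: Genome, config: SimConfig, seed: int,
                            n_reads: int | None = None) -> list[ReadRecord]:
    """Chimeric artifact reads joining two random genome positions.

    These model mapping/library artifacts: the two segments respect the
    junction caller's geometric constraints (same chromosome, separation
    51–20,000 bp, at least 10 bases on each side) but fall at arbitrary
    sequence, so their apparent intron boundaries carry random
    dinucleotides.  Used to calibrate the control-dinucleotide FDR.
    """
    rng = np.random.default_rng(seed)
    n = config.n_artifact_reads if n_reads is None else n_reads
    L = config.read_length
    reads: list[ReadRecord] = []
    chroms = genome.chrom_names
    for serial in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        glen = genome.length(chrom)
        b = int(rng.integers(10, L - 9))
        sep = int(rng.integers(51, 5001))
        left = int(rng.integers(0, glen - (L + sep)))
        istart = left + b
        iend = istart + sep
        seq = genome.fetch(chrom, left, istart) + genome.fetch(chrom, iend, iend + (L - b))
        reads.append(ReadRecord(
            f"art{serial}|v=X|c={chrom}|s={istart}|e={iend}|b={b}", seq))
    return reads
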