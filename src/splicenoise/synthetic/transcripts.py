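"""Transcript-level simulation of splicing errors.

Each pre-mRNA copy splices every intron independently: with probability
1 − ε(intron) the true sites are used; otherwise a cryptic donor GT (or
acceptor AG) is chosen from the intron and up to 30 bp of flanking exon,
weighted by a geometric decay with distance from the true site.  Error
isoforms that disrupt the downstream reading frame survive to the mature
mRNA pool with probability ``frame_bias`` relative to frame-preserving
ones — a minimal proxy for nonsense-mediated decay.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .._seq import revcomp
from ..config import SimConfig
from .genome import Genome
from .truth import GeneModel, TruthSet, Variant, junction_key


def intron_error_prob(config: SimConfig, length: int) -> float:
    """Per-intron cryptic-splicing probability, optionally length-dependent."""
    eps = config.per_intron_error_rate + config.error_length_slope * math.log10(length)
    return float(min(max(eps, 0.0), 0.5))


def _triple_cap(h: int) -> int:
    """Largest x <= h with x ≡ 2 (mod 3).

    Candidate offsets on each side of the true site span complete
    distance triples {3k, 3k+1, 3k+2}; together with the triple-constant
    weight this keeps the three reading-frame classes exchangeable, so
    with no NMD bias exactly 1/3 of proposed cryptic sites preserve
    frame.
    """
    return h - ((h - 2) % 3)


def _kernel_weight(off: int, decay: float) -> float:
    # geometric decay across distance triples, constant within a triple
    return decay ** (3 * (abs(off) // 3))


def _donor_candidates(genome: Genome, gene: GeneModel, s: int, e: int,
                      cfg: SimConfig) -> list[Variant]:
    """Cryptic donors: sense-GT positions near the true donor."""
    out = []
    seq = genome.seq(gene.chrom)
    lo = -_triple_cap(cfg.cryptic_exon_flank)
    hi = _triple_cap(min(cfg.cryptic_max_offset, (e - s) - 51))
    for off in range(lo, hi + 1):
        if abs(off) < cfg.cryptic_min_offset:
            continue
        if gene.strand == "+":
            p = s + off
            ok = seq[p:p + 2] == "GT"
            ns, ne = p, e
        else:
            p = e - off  # new intron end; sense donor dinuc is rc(seq[p-2:p])
            ok = seq[p - 2:p] == "AC"
            ns, ne = s, p
        if ok and 50 < ne - ns <= cfg.intron_length_max:
            out.append(Variant("D", off, ns, ne, off % 3 == 0,
                               _kernel_weight(off, cfg.cryptic_decay)))
    return out


def _acceptor_candidates(genome: Genome, gene: GeneModel, s: int, e: int,
                         cfg: SimConfig) -> list[Variant]:
    """Cryptic acceptors: sense-AG positions near the true acceptor."""
    out = []
    seq = genome.seq(gene.chrom)
    lo = -_triple_cap(min(cfg.cryptic_max_offset, (e - s) - 51))
    hi = _triple_cap(cfg.cryptic_exon_flank)
    for off in range(lo, hi + 1):
        if abs(off) < cfg.cryptic_min_offset:
            continue
        if gene.strand == "+":
            p = e + off  # new intron end
            ok = seq[p - 2:p] == "AG"
            ns, ne = s, p
        else:
            p = s - off  # new intron start; sense acceptor dinuc is rc(seq[p:p+2])
            ok = seq[p:p + 2] == "CT"
            ns, ne = p, e
        if ok and 50 < ne - ns <= cfg.intron_length_max:
            out.append(Variant("A", off, ns, ne, off % 3 == 0,
                               _kernel_weight(off, cfg.cryptic_decay)))
    return out


def enumerate_cryptic_variants(genome: Genome, genes: list[GeneModel],
                               config: SimConfig) -> dict[tuple[str, int], list[Variant]]:
    """All cryptic splice choices available to each intron.

    Variants whose intron interval would coincide with a true junction are
    excluded so the true/error junction sets stay disjoint.
    """
    true_keys = {k for g in genes for k in g.intron_keys()}
    variants: dict[tuple[str, int], list[Variant]] = {}
    for gene in genes:
        for ii, (s, e) in enumerate(gene.introns):
            cands = (_donor_candidates(genome, gene, s, e, config)
                     + _acceptor_candidates(genome, gene, s, e, config))
            cands = [v for v in cands
                     if junction_key(gene.chrom, gene.strand, v.start, v.end)
                     not in true_keys]
            variants[(gene.gene_id, ii)] = cands
    return variants


def _draw_expression(genes: list[GeneModel], introns: pd.DataFrame,
                     config: SimConfig, rng: np.random.Generator) -> dict[str, float]:
    w = 1.0 + rng.pareto(config.expression_alpha, size=len(genes))
    if config.expression_length_coupling != 0.0:
        mean_len = introns.groupby("gene_id")["length"].mean()
        med = float(mean_len.median())
        fac = np.array([(mean_len.get(g.gene_id, med) / med)
                        ** (-config.expression_length_coupling) for g in genes])
        w = w * fac
    w = w / w.mean()
    return {g.gene_id: float(x) for g, x in zip(genes, w)}


def build_truth(genome: Genome, genes: list[GeneModel], introns: pd.DataFrame,
                config: SimConfig, rng: np.random.Generator) -> TruthSet:
    introns = introns.copy()
    introns["eps"] = [intron_error_prob(config, L) for L in introns["length"]]
    variants = enumerate_cryptic_variants(genome, genes, config)
    expression = _draw_expression(genes, introns, config, rng)
    truth = TruthSet(genes=genes, introns=introns, expression=expression,
                     variants=variants)
    truth.check_invariants()
    return truth


def _pick_variants(cands: list[Variant], k: int, cfg: SimConfig,
                   rng: np.random.Generator) -> list[Variant]:
    """Draw k error events from the kernel, with NMD thinning.

    Frame-disrupting choices survive with probability ``frame_bias``;
    degraded transcripts vanish from the pool (they are not resampled).
    """
    if not cands or k == 0:
        return []
    w = np.array([v.weight for v in cands])
    w = w / w.sum()
    idx = rng.choice(len(cands), size=k, p=w)
    kept = []
    for i in idx:
        v = cands[i]
        if v.in_frame or cfg.frame_bias >= 1.0 or rng.random() < cfg.frame_bias:
            kept.append(v)
    return kept


def simulate_junction_counts(genome: Genome, truth: TruthSet, config: SimConfig,
                             seed: int, total_reads: int | None = None
                             ) -> pd.DataFrame:
    """Junction-spanning read counts per splice variant, without read sequences.

    For each true intron the number of spanning reads is Poisson with mean
    ``depth`` scaled by the gene's expression weight (or scaled so the
    total is ``total_reads`` if given); each read independently derives
    from an error isoform with probability ε(intron).  Returns one row per
    observed junction with its read count and truth labels.
    """
    rng = np.random.default_rng(seed)
    introns = truth.introns
    w = np.array([truth.expression[g] for g in introns["gene_id"]])
    mean = config.depth * w
    if total_reads is not None:
        mean = mean * (total_reads / mean.sum())
    n_reads = rng.poisson(mean)

    rows = []
    for (_, row), n in zip(introns.iterrows(), n_reads):
        if n == 0:
            continue
        gid, ii = row["gene_id"], int(row["intron_idx"])
        k_err = rng.binomial(n, row["eps"])
        cands = truth.variants[(gid, ii)]
        kept = _pick_variants(cands, int(k_err), config, rng)
        if k_err and not cands:
            truth.retained_introns.append((gid, ii))
        base = dict(chrom=row["chrom"], strand=row["strand"], gene_id=gid,
                    intron_idx=ii)
        rows.append(dict(base, start=int(row["start"]), end=int(row["end"]),
                         reads=int(n - k_err), is_error=False, side="T",
                         offset=0, in_frame=True))
        if kept:
            counts: dict[Variant, int] = {}
            for v in kept:
                counts[v] = counts.get(v, 0) + 1
            for v, c in counts.items():
                key = junction_key(row["chrom"], row["strand"], v.start, v.end)
                truth.record_error_junction(key, gid, ii, v.side, v.offset)
                rows.append(dict(base, start=v.start, end=v.end, reads=c,
                                 is_error=True, side=v.side, offset=v.offset,
                                 in_frame=v.in_frame))
    df = pd.DataFrame(rows)
    if len(df):
        df = (df[df["reads"] > 0]
              .groupby(["chrom", "strand", "start", "end", "gene_id", "intron_idx",
                        "is_error", "side", "offset", "in_frame"], as_index=False)
              ["reads"].sum())
    return df


def simulate_transcripts(genome: Genome, truth: TruthSet, config: SimConfig,
                         seed: int, n_transcripts: int = 10_000) -> pd.DataFrame:
    """Simulate a labelled isoform pool.

    Transcripts are allocated to genes by expression weight; each records
    which introns (if any) mis-spliced and to which cryptic variant.
    Returns one row per transcript group: gene, error count, frame class.
    The per-transcript labels are also stored on ``truth.isoform_labels``.
    """
    rng = np.random.default_rng(seed)
    genes = truth.genes
    w = np.array([truth.expression[g.gene_id] for g in genes], dtype=float)
    alloc = rng.multinomial(n_transcripts, w / w.sum())
    rows = []
    for gene, n in zip(genes, alloc):
        if n == 0:
            continue
        gi = truth.introns[truth.introns["gene_id"] == gene.gene_id]
        eps = gi["eps"].to_numpy()
        if len(eps) == 0:
            rows.append(dict(gene_id=gene.gene_id, n=int(n), n_errors=0,
                             n_in_frame=0, survived=int(n)))
            continue
        err = rng.random((n, len(eps))) < eps[None, :]
        any_err = err.any(axis=1)
        n_clean = int(n - any_err.sum())
        if n_clean:
            rows.append(dict(gene_id=gene.gene_id, n=n_clean, n_errors=0,
                             n_in_frame=0, survived=n_clean))
        for t in np.nonzero(any_err)[0]:
            hit = np.nonzero(err[t])[0]
            n_err = n_if = 0
            dead = False
            for ii in hit:
                cands = truth.variants[(gene.gene_id, int(ii))]
                kept = _pick_variants(cands, 1, config, rng)
                if not cands:
                    truth.retained_introns.append((gene.gene_id, int(ii)))
                    n_err += 1  # intron retention fallback
                elif kept:
                    n_err += 1
                    n_if += int(kept[0].in_frame)
                else:
                    dead = True  # degraded by the NMD proxy
                    break
            rows.append(dict(gene_id=gene.gene_id, n=1, n_errors=n_err,
                             n_in_frame=n_if, survived=int(not dead)))
    df = pd.DataFrame(rows)
    truth.isoform_labels = df
    return df


def isoform_sequence(genome: Genome, gene: GeneModel,
                     variant_map: dict[int, Variant] | None = None) -> str:
    """Spliced sense sequence of an isoform.

    ``variant_map`` maps intron index -> cryptic Variant; missing introns
    splice at their true sites.
    """
    exons = [list(x) for x in gene.exons]
    # intron ii sits between exons ii and ii+1; a variant moves both edges
    if variant_map:
        for ii, v in variant_map.items():
            exons[ii][1] = v.start
            exons[ii + 1][0] = v.end
    seq = "".join(genome.fetch(gene.chrom, s, e) for s, e in exons)
    return seq if gene.strand == "+" else revcomp(seq)
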