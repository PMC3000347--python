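"""De novo splice-junction discovery from short reads.

Reads that fail contiguous alignment are split into their first and last
20 bases; each end is looked up in an exact k-mer seed index.  When both
ends map uniquely to the same strand of the same chromosome, 51–20,000 bp
apart and in order, every breakpoint with at least ``min_overhang`` bases
on each side is scored and the placement(s) with the fewest mismatches
are reported.  When exactly one end maps, the alignment is extended
base-by-base without mismatches and the remainder of the read is searched
for a unique perfect match within 20 kb.  Because intron boundaries often
sit in locally repeated sequence, each candidate junction carries an
equivalence class of coordinate-shifted placements that reconstruct the
identical read; the canonical placement is the one whose intron starts
GT (or GC) and ends AG, preferring GT-AG, then GC-AG, then the leftmost.

Uniqueness follows bwa-like semantics at toy scale: a full-length
alignment is unique when exactly one locus achieves the minimum mismatch
count and no second locus comes within one mismatch of it; end seeds are
exact matches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import revcomp, seq_to_array
from .config import RunConfig
from .synthetic.genome import Genome

logger = logging.getLogger(__name__)

CANONICAL_PAIRS = (("GT", "AG"), ("GC", "AG"))
CONTROL_PAIRS = (("GT", "TC"), ("GC", "TC"))


@dataclass(frozen=True)
class EndAlignment:
    """Unique placement of one 20-base read end."""

    read_id: str
    end: str  # "first" | "last"
    chrom: str
    strand: str
    pos: int  # 0-based start of the 20-mer on the forward genome
    mismatches: int = 0
    unique: bool = True


@dataclass(frozen=True)
class FullAlignment:
    chrom: str
    strand: str
    pos: int
    mismatches: int


@dataclass
class JunctionCandidate:
    """One read's evidence for an intron interval.

    ``placements`` lists every coordinate shift consistent with the same
    read; ``start``/``end`` give the canonical placement.
    """

    chrom: str
    strand: str
    start: int
    end: int
    read_id: str
    breakpoint: int
    mismatches: int
    placements: list[tuple[int, int]] = field(default_factory=list)
    dinucs: list[tuple[str, str]] = field(default_factory=list)


class SeedIndex:
    """Exact k-mer index of the forward genome."""

    def __init__(self, genome: Genome, k: int = 20):
        if k < 12:
            raise ValueError("seed length must be >= 12")
        self.k = k
        self.genome = genome
        self._index: dict[str, list[tuple[str, int]]] = {}
        n_kmers = 0
        for chrom, seq in genome.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((chrom, i))
                n_kmers += 1
        if n_kmers == 0:
            logger.warning("genome contains no indexable %d-mers", k)

    def query(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])

    def __len__(self) -> int:
        return sum(len(v) for v in self._index.values())


def build_index(genome: Genome, k: int = 20) -> SeedIndex:
    return SeedIndex(genome, k)


def _sense_dinucs(genome: Genome, chrom: str, strand: str,
                  start: int, end: int) -> tuple[str, str]:
    """(donor, acceptor) dinucleotides in transcription orientation."""
    left = genome.fetch(chrom, start, start + 2)
    right = genome.fetch(chrom, end - 2, end)
    if strand == "+":
        return left, right
    return revcomp(right), revcomp(left)


def map_contiguous(read: str, index: SeedIndex, genome: Genome,
                   max_mismatches: int = 2) -> FullAlignment | None:
    """Best unique full-length alignment of a read, or None.

    Seed candidates come from exact matches of the first and last k bases
    in either orientation; each candidate locus is verified by full
    Hamming comparison.
    """
    L = len(read)
    k = index.k
    if L < k:
        return None
    loci: set[tuple[str, str, int]] = set()
    for strand, r in (("+", read), ("-", revcomp(read))):
        for end_seq, off in ((r[:k], 0), (r[-k:], L - k)):
            for chrom, p in index.query(end_seq):
                start = p - off
                if start >= 0 and start + L <= genome.length(chrom):
                    loci.add((strand, chrom, start))
    if not loci:
        return None
    scored = []
    rarrs = {"+": seq_to_array(read), "-": seq_to_array(revcomp(read))}
    for strand, chrom, start in loci:
        garr = genome.array(chrom)
        mism = int(np.count_nonzero(rarrs[strand] != garr[start:start + L]))
        if mism <= max_mismatches + 1:
            scored.append((mism, strand, chrom, start))
    if not scored:
        return None
    scored.sort()
    best = scored[0]
    if best[0] > max_mismatches:
        return None
    # unique: single best locus, no runner-up within one mismatch
    if len(scored) > 1 and scored[1][0] <= best[0] + 1:
        return None
    return FullAlignment(chrom=best[2], strand=best[1], pos=best[3],
                         mismatches=best[0])


def split_map(read: str, index: SeedIndex, read_id: str = ""
              ) -> dict[str, tuple[EndAlignment | None, EndAlignment | None,
                                   int, int]]:
    """Map the first and last k bases of the read, in both orientations.

    Returns, per orientation ('+' = read as given, '-' = reverse
    complement), the unique end alignments (or None) along with the raw
    hit counts for each end.
    """
    k = index.k
    out = {}
    for strand, r in (("+", read), ("-", revcomp(read))):
        first_hits = index.query(r[:k]) if "N" not in r[:k] else []
        last_hits = index.query(r[-k:]) if "N" not in r[-k:] else []
        first = last = None
        if len(first_hits) == 1:
            chrom, p = first_hits[0]
            first = EndAlignment(read_id, "first", chrom, strand, p)
        if len(last_hits) == 1:
            chrom, p = last_hits[0]
            last = EndAlignment(read_id, "last", chrom, strand, p)
        out[strand] = (first, last, len(first_hits), len(last_hits))
    return out


def enumerate_junctions(read: str, first: EndAlignment, last: EndAlignment,
                        genome: Genome, cfg: RunConfig | None = None,
                        read_id: str = "") -> list[JunctionCandidate]:
    """All minimum-mismatch junction placements consistent with two mapped ends.

    ``read`` must already be in the orientation of the end alignments.
    """
    cfg = cfg or RunConfig()
    L = len(read)
    if first.chrom != last.chrom or first.strand != last.strand:
        return []
    ls = first.pos
    right_end = last.pos + 20
    intron_len = (right_end - ls) - L
    if not (cfg.min_intron - 1 < intron_len <= cfg.max_intron):
        return []
    garr = genome.array(first.chrom)
    if ls < 0 or right_end > len(garr) or right_end - L < 0:
        return []
    rarr = seq_to_array(read)
    dl = (rarr != garr[ls:ls + L]).astype(np.int32)
    dr = (rarr != garr[right_end - L:right_end]).astype(np.int32)
    cuml = np.concatenate(([0], np.cumsum(dl)))
    cumr = np.concatenate(([0], np.cumsum(dr)))
    total_r = cumr[-1]
    bs = np.arange(cfg.min_overhang, L - cfg.min_overhang + 1)
    tot = cuml[bs] + (total_r - cumr[bs])
    m = int(tot.min())
    if m > cfg.max_mismatches:
        return []
    out = []
    for b in bs[tot == m]:
        s = ls + int(b)
        out.append(JunctionCandidate(first.chrom, first.strand, s,
                                     s + intron_len, read_id, int(b), m))
    return out


def extend_and_search(read: str, end: EndAlignment, genome: Genome,
                      cfg: RunConfig | None = None, read_id: str = ""
                      ) -> JunctionCandidate | None:
    """One-end rescue: extend without mismatches, then search for the rest.

    The remainder (>= ``min_overhang`` bases) must match perfectly at
    exactly one position within ``max_intron`` of the extension point
    (downstream for a mapped first end, upstream for a mapped last end).
    """
    cfg = cfg or RunConfig()
    L = len(read)
    seq = genome.seq(end.chrom)
    glen = len(seq)
    if end.end == "first":
        p = end.pos
        b = 20
        while b < L - 1 and p + b < glen and read[b] == seq[p + b]:
            b += 1
        if b > L - cfg.min_overhang:
            return None
        rem = read[b:]
        left_end = p + b
        lo = left_end + cfg.min_intron
        hi = min(left_end + cfg.max_intron, glen - len(rem))
        hits = _find_all(seq, rem, lo, hi)
        if len(hits) != 1:
            return None
        s, e = left_end, hits[0]
        return JunctionCandidate(end.chrom, end.strand, s, e, read_id, b, 0)
    # mapped last end: extend leftwards
    p = end.pos
    i = 0
    while (20 + i) < L - 1 and p - 1 - i >= 0 and read[L - 21 - i] == seq[p - 1 - i]:
        i += 1
    m = 20 + i
    b = L - m
    if b < cfg.min_overhang:
        return None
    rem = read[:b]
    right_start = p - i
    lo = max(right_start - cfg.max_intron - b, 0)
    hi = right_start - cfg.min_intron - b
    hits = _find_all(seq, rem, lo, hi)
    if len(hits) != 1:
        return None
    s, e = hits[0] + b, right_start
    if not (cfg.min_intron - 1 < e - s <= cfg.max_intron):
        return None
    return JunctionCandidate(end.chrom, end.strand, s, e, read_id, b, 0)


def _find_all(seq: str, pattern: str, lo: int, hi: int) -> list[int]:
    """Start positions of every occurrence of pattern with start in [lo, hi]."""
    hits = []
    stop = hi + len(pattern)
    i = seq.find(pattern, max(lo, 0), stop)
    while i != -1:
        hits.append(i)
        i = seq.find(pattern, i + 1, stop)
    return hits


def shift_equivalence(candidate: JunctionCandidate, genome: Genome,
                      max_shift: int = 20) -> JunctionCandidate:
    """Populate the equivalence class and canonicalize the placement.

    A shift of the intron by t bases reconstructs the identical read iff
    the t bases entering the intron on one side equal those leaving it on
    the other; valid shifts form a contiguous range around 0.
    """
    s, e = candidate.start, candidate.end
    seq = genome.seq(candidate.chrom)
    glen = len(seq)
    shifts = [0]
    t = 1
    while t <= max_shift and e + t <= glen and seq[s + t - 1] == seq[e + t - 1]:
        shifts.append(t)
        t += 1
    t = -1
    while t >= -max_shift and s + t >= 0 and seq[s + t] == seq[e + t]:
        shifts.append(t)
        t -= 1
    shifts.sort()
    placements = [(s + t, e + t) for t in shifts]
    dinucs = [_sense_dinucs(genome, candidate.chrom, candidate.strand, a, b)
              for a, b in placements]
    best = None
    for rank, pair in enumerate(CANONICAL_PAIRS):
        for (a, b), d in zip(placements, dinucs):
            if d == pair:
                best = (a, b)
                break
        if best:
            break
    if best is None:
        best = placements[0]
    candidate.placements = placements
    candidate.dinucs = dinucs
    candidate.start, candidate.end = best
    return candidate


def classify_dinucs(dinucs: list[tuple[str, str]]) -> str:
    """Dinucleotide class of a junction from its placements' sense pairs."""
    if any(d in CANONICAL_PAIRS for d in dinucs):
        return "GT-AG" if ("GT", "AG") in dinucs else "GC-AG"
    if any(d in CONTROL_PAIRS for d in dinucs):
        return "control"
    return "other"


def aggregate_junctions(candidates: dict[int, list[JunctionCandidate]],
                        genome: Genome) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-read candidates into a junction table.

    ``candidates`` maps a read index to its minimum-mismatch candidates
    (already canonicalized).  Reads supporting several distinct junctions
    at equal mismatch count are counted once per junction and flagged
    ambiguous.  Returns ``(junctions, assignments)``; assignments link
    read index -> junction row for subsampling analyses.
    """
    keys: dict[tuple, int] = {}
    rows: list[dict] = []
    assign: list[tuple[int, int]] = []
    for ridx, cands in candidates.items():
        seen = {}
        for c in cands:
            key = (c.chrom, c.strand, c.start, c.end)
            if key in seen:
                continue
            seen[key] = c
        ambiguous = len(seen) > 1
        for key, c in seen.items():
            if key not in keys:
                keys[key] = len(rows)
                rows.append(dict(chrom=c.chrom, strand=c.strand, start=c.start,
                                 end=c.end, reads=0, ambiguous_reads=0,
                                 n_placements=len(c.placements),
                                 dinuc_class=classify_dinucs(c.dinucs),
                                 min_mismatches=c.mismatches))
            j = keys[key]
            rows[j]["reads"] += 1
            rows[j]["ambiguous_reads"] += int(ambiguous)
            rows[j]["min_mismatches"] = min(rows[j]["min_mismatches"], c.mismatches)
            assign.append((ridx, j))
    junctions = pd.DataFrame(rows, columns=["chrom", "strand", "start", "end",
                                            "reads", "ambiguous_reads",
                                            "n_placements", "dinuc_class",
                                            "min_mismatches"])
    assignments = pd.DataFrame(assign, columns=["read_idx", "junction_idx"])
    return junctions, assignments


def discover_junctions(reads, genome: Genome, index: SeedIndex | None = None,
                       cfg: RunConfig | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Full junction discovery over a collection of reads.

    ``reads`` is a sequence of (read_id, sequence) pairs.  Returns the
    junction table, read->junction assignments, and a stage-count summary.
    Contiguously mapping reads are excluded from the junction search;
    short reads (< 40 bp) with both ends uniquely mapped are discarded.
    """
    cfg = cfg or RunConfig()
    if index is None:
        index = build_index(genome, cfg.seed_length)
    canon_cache: dict[tuple, JunctionCandidate] = {}
    keys: dict[tuple, int] = {}
    rows: list[dict] = []
    assign_reads: list[int] = []
    assign_juncs: list[int] = []
    stats = dict(n_reads=0, contiguous=0, both_end=0, one_end=0,
                 short_discarded=0, unmapped=0)

    for ridx, (rid, seq) in enumerate(reads):
        stats["n_reads"] += 1
        L = len(seq)
        if map_contiguous(seq, index, genome, cfg.max_mismatches) is not None:
            stats["contiguous"] += 1
            continue
        ends = split_map(seq, index, rid)
        found: list[JunctionCandidate] = []
        for strand in ("+", "-"):
            r = seq if strand == "+" else revcomp(seq)
            first, last, nf, nl = ends[strand]
            if first is not None and last is not None:
                if L < 40 and cfg.discard_short_both_end:
                    stats["short_discarded"] += 1
                    continue
                cands = enumerate_junctions(r, first, last, genome, cfg, rid)
                if cands:
                    stats["both_end"] += 1
                    found.extend(cands)
                continue
            single = first if (first is not None and nl != 1) else (
                last if (last is not None and nf != 1) else None)
            if single is not None:
                c = extend_and_search(r, single, genome, cfg, rid)
                if c is not None:
                    stats["one_end"] += 1
                    found.append(c)
        if not found:
            stats["unmapped"] += 1
            continue
        # canonicalize (cached per raw interval) and aggregate streaming
        seen: dict[tuple, JunctionCandidate] = {}
        for c in found:
            key = (c.chrom, c.strand, c.start, c.end)
            cached = canon_cache.get(key)
            if cached is None:
                shift_equivalence(c, genome)
                canon_cache[key] = cached = c
            ckey = (cached.chrom, cached.strand, cached.start, cached.end)
            prev = seen.get(ckey)
            if prev is None or c.mismatches < prev.mismatches:
                seen[ckey] = JunctionCandidate(
                    cached.chrom, cached.strand, cached.start, cached.end,
                    rid, c.breakpoint, c.mismatches, cached.placements,
                    cached.dinucs)
        ambiguous = len(seen) > 1
        for ckey, c in seen.items():
            j = keys.get(ckey)
            if j is None:
                j = keys[ckey] = len(rows)
                rows.append(dict(chrom=c.chrom, strand=c.strand, start=c.start,
                                 end=c.end, reads=0, ambiguous_reads=0,
                                 n_placements=len(c.placements),
                                 dinuc_class=classify_dinucs(c.dinucs),
                                 min_mismatches=c.mismatches))
            rows[j]["reads"] += 1
            rows[j]["ambiguous_reads"] += int(ambiguous)
            rows[j]["min_mismatches"] = min(rows[j]["min_mismatches"], c.mismatches)
            assign_reads.append(ridx)
            assign_juncs.append(j)

    junctions = pd.DataFrame(rows, columns=["chrom", "strand", "start", "end",
                                            "reads", "ambiguous_reads",
                                            "n_placements", "dinuc_class",
                                            "min_mismatches"])
    assignments = pd.DataFrame({"read_idx": np.array(assign_reads, dtype=np.int64),
                                "junction_idx": np.array(assign_juncs, dtype=np.int64)})
    stats["n_junctions"] = len(junctions)
    logger.info("discover_junctions: %s", stats)
    return junctions, assignments, stats
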