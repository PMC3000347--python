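"""Hexamer enrichment near noise splice sites.

"Noise" splice sites are unannotated, unconserved sites spliced to an
annotated partner and more than 50 bp from any annotated site.  Each is
matched to a decoy: the nearest unused GT (or AG, for acceptors)
dinucleotide between the noise site and its annotated partner, never
observed as spliced.  Hexamer frequencies in the exonic and intronic
flanks of noise vs decoy sites are compared per hexamer with a 2x2
chi-square (this hexamer vs all others), Bonferroni-corrected over the
4096 hexamers; the log2 enrichment uses a pseudocount of one on all four
cells.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import revcomp, seq_to_array
from .annotation import Annotation, SiteKey, junction_sites
from .config import RunConfig
from .synthetic.genome import Genome

logger = logging.getLogger(__name__)

HEXAMERS = ["".join(p) for p in itertools.product("ACGT", repeat=6)]
_HEX_INDEX = {h: i for i, h in enumerate(HEXAMERS)}


@dataclass
class NoiseSite:
    site: SiteKey
    partner: SiteKey
    nearest_annotated_distance: int


@dataclass
class DecoySite:
    noise: NoiseSite
    position: int  # boundary coordinate of the hypothetical intron edge


# ------------------------------------------------------------- site selection

def select_noise_and_decoy(junctions: pd.DataFrame, labels: dict[SiteKey, str],
                           annotation: Annotation, genome: Genome,
                           cfg: RunConfig | None = None
                           ) -> tuple[list[NoiseSite], list[DecoySite]]:
    """Noise splice sites and their matched unused-dinucleotide decoys.

    A junction qualifies when exactly one end is annotated; the other end
    must be unconserved and > ``near_annotated_bp`` from any annotated
    site of its type.  The decoy is the unused GT/AG closest to the noise
    site, strictly between it and the annotated partner site.
    """
    cfg = cfg or RunConfig()
    used_boundaries: dict[tuple[str, str, str], set[int]] = {}
    for row in junctions.itertuples(index=False):
        d, a = junction_sites(row.chrom, row.strand, int(row.start), int(row.end))
        for s in (d, a):
            used_boundaries.setdefault((s[0], s[1], s[2]), set()).add(s[3])

    noise_sites: list[NoiseSite] = []
    for row in junctions.itertuples(index=False):
        d, a = junction_sites(row.chrom, row.strand, int(row.start), int(row.end))
        d_ann = d in annotation.donor_sites
        a_ann = a in annotation.acceptor_sites
        if d_ann == a_ann:
            continue
        cand, partner = (a, d) if d_ann else (d, a)
        if annotation.is_annotated_site(cand):
            continue
        if labels.get(cand) != "unconserved":
            continue
        dist = annotation.nearest_site_distance(cand)
        if dist <= cfg.near_annotated_bp:
            continue
        noise_sites.append(NoiseSite(cand, partner, dist))

    decoys: list[DecoySite] = []
    kept: list[NoiseSite] = []
    dropped = 0
    for ns in noise_sites:
        pos = _find_decoy(ns, used_boundaries, genome)
        if pos is None:
            dropped += 1
            continue
        kept.append(ns)
        decoys.append(DecoySite(ns, pos))
    if dropped:
        logger.info("dropped %d noise sites without an eligible decoy", dropped)
    if not kept:
        raise ValueError(
            f"no noise sites selected (candidates={len(noise_sites)}, "
            f"dropped={dropped}); check labels and annotation")
    return kept, decoys


def _dinuc_positions_for(site_type: str, strand: str) -> tuple[str, int]:
    """(forward-genome dinucleotide, boundary offset) for a site type/strand.

    Returns the dinucleotide to search on the forward strand and the
    offset from the dinucleotide start to the boundary coordinate.
    """
    if site_type == "5":
        return ("GT", 0) if strand == "+" else ("AC", 2)
    return ("AG", 2) if strand == "+" else ("CT", 0)


def _find_decoy(ns: NoiseSite, used: dict[tuple[str, str, str], set[int]],
                genome: Genome) -> int | None:
    chrom, strand, typ, pos = ns.site
    lo, hi = sorted((pos, ns.partner[3]))
    seq = genome.seq(chrom)
    dinuc, boundary_off = _dinuc_positions_for(typ, strand)
    taken = used.get((chrom, strand, typ), set())
    best = None
    i = seq.find(dinuc, max(lo - 2, 0))
    while i != -1 and i <= hi:
        b = i + boundary_off
        if lo < b < hi and b != pos and b not in taken:
            if best is None or abs(b - pos) < abs(best - pos):
                best = b
        i = seq.find(dinuc, i + 1)
    return best


# ------------------------------------------------------------ flank extraction

def extract_flanks(sites: list[SiteKey], genome: Genome,
                   cfg: RunConfig | None = None
                   ) -> tuple[list[str], list[str]]:
    """Exonic and intronic flanking windows of splice sites, sense-oriented.

    Windows span ``motif_window`` bases on each side of the boundary; an
    exclusion zone is removed next to the site (5' sites: 5 exonic and 5
    intronic bases; 3' sites: 2 exonic and 20 intronic), since those
    bases carry the splice-site consensus itself.  Sequences are returned
    5'→3' in the transcript sense; windows truncated at contig edges are
    flagged via a log message.
    """
    cfg = cfg or RunConfig()
    w = cfg.motif_window
    exonic, intronic = [], []
    truncated = 0
    for site in sites:
        chrom, strand, typ, pos = site
        ex_skip, in_skip = (5, 5) if typ == "5" else (2, 20)
        glen = genome.length(chrom)
        intron_at_start = (strand == "+") == (typ == "5")
        if intron_at_start:
            ex_iv = (pos - w, pos - ex_skip)
            in_iv = (pos + in_skip, pos + w)
        else:
            ex_iv = (pos + ex_skip, pos + w)
            in_iv = (pos - w, pos - in_skip)
        if ex_iv[0] < 0 or in_iv[0] < 0 or ex_iv[1] > glen or in_iv[1] > glen:
            truncated += 1
        ex = genome.fetch_sense(chrom, max(ex_iv[0], 0), ex_iv[1], strand)
        iv = genome.fetch_sense(chrom, max(in_iv[0], 0), in_iv[1], strand)
        exonic.append(ex)
        intronic.append(iv)
    if truncated:
        logger.warning("%d flank windows truncated at contig edges", truncated)
    return exonic, intronic


# ------------------------------------------------------------ hexamer counting

def hexamer_counts(sequences: list[str]) -> np.ndarray:
    """Overlapping hexamer counts over all 4096 hexamers.

    Windows containing N are skipped; the total equals the sum of
    max(0, len - 5) over N-free stretches.
    """
    counts = np.zeros(4096, dtype=np.int64)
    mult = 4 ** np.arange(5, -1, -1)
    for seq in sequences:
        if len(seq) < 6:
            continue
        codes = np.full(len(seq), 4, dtype=np.int64)
        arr = seq_to_array(seq)
        for i, b in enumerate(b"ACGT"):
            codes[arr == b] = i
        valid = codes < 4
        ids = np.zeros(len(seq) - 5, dtype=np.int64)
        ok = np.ones(len(seq) - 5, dtype=bool)
        for k in range(6):
            ids += codes[k:len(seq) - 5 + k] * mult[k]
            ok &= valid[k:len(seq) - 5 + k]
        counts += np.bincount(ids[ok], minlength=4096)
    return counts


# ------------------------------------------------------------ enrichment tests

def enrichment_test(counts_noise: np.ndarray, counts_decoy: np.ndarray,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Per-hexamer 2x2 chi-square of noise vs decoy frequencies.

    Cells: (this hexamer, all others) x (noise, decoy).  Expected cells
    below 5 fall back to Fisher's exact test (flagged).  Significance is
    Bonferroni-corrected over 4096 hexamers; log2 enrichment applies a
    pseudocount of 1 to all four cells.
    """
    tn, td = int(counts_noise.sum()), int(counts_decoy.sum())
    if tn == 0 or td == 0:
        raise ValueError("hexamer totals must be positive")
    a = counts_noise.astype(float)
    b = counts_decoy.astype(float)
    rest_n = tn - a
    rest_d = td - b
    # chi-square for 2x2 without continuity correction, vectorized
    n_tot = tn + td
    row1 = a + b
    row2 = rest_n + rest_d
    col1 = a + rest_n  # = tn
    col2 = b + rest_d  # = td
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = (n_tot * (a * rest_d - b * rest_n) ** 2
                / (row1 * row2 * col1 * col2))
    chi2 = np.where(row1 > 0, chi2, 0.0)
    pvals = stats.chi2.sf(chi2, df=1)
    pvals = np.where(row1 > 0, pvals, 1.0)
    expected_min = np.minimum(row1 * tn, row1 * td) / n_tot
    exact_mask = expected_min < 5
    for i in np.nonzero(exact_mask)[0]:
        table = [[int(counts_noise[i]), int(counts_decoy[i])],
                 [int(tn - counts_noise[i]), int(td - counts_decoy[i])]]
        pvals[i] = stats.fisher_exact(table)[1]
    log2_enr = np.log2(((a + 1) / (tn + 1)) / ((b + 1) / (td + 1)))
    p_adj = np.minimum(pvals * 4096, 1.0)
    return pd.DataFrame(dict(
        hexamer=HEXAMERS, count_noise=counts_noise, count_decoy=counts_decoy,
        log2_enrichment=log2_enr, chi2=np.where(exact_mask, np.nan, chi2),
        p=pvals, p_adj=p_adj, significant=p_adj < alpha, exact=exact_mask))


def ese_overlap(enrichment_5: pd.DataFrame, enrichment_3: pd.DataFrame,
                ese_list: list[str]) -> dict:
    """Fraction of a reference ESE set enriched exonic of both site types.

    Also reports a chi-square of ESE membership against the sign of the
    exonic enrichment (pooled over both site types).
    """
    ese = set()
    for h in ese_list:
        h = h.strip().upper()
        if len(h) != 6 or any(c not in "ACGT" for c in h):
            raise ValueError(f"malformed hexamer in ESE list: {h!r}")
        ese.add(h)
    if not ese:
        return dict(n_ese=0, overlap_fraction=float("nan"))
    e5 = enrichment_5.set_index("hexamer")["log2_enrichment"]
    e3 = enrichment_3.set_index("hexamer")["log2_enrichment"]
    both_pos = [(e5[h] > 0) and (e3[h] > 0) for h in sorted(ese)]
    frac = float(np.mean(both_pos))
    membership = np.array([h in ese for h in HEXAMERS])
    pos = ((e5.reindex(HEXAMERS) > 0) & (e3.reindex(HEXAMERS) > 0)).to_numpy()
    table = [[int((membership & pos).sum()), int((membership & ~pos).sum())],
             [int((~membership & pos).sum()), int((~membership & ~pos).sum())]]
    if min(min(r) for r in table) < 5:
        p = stats.fisher_exact(table)[1]
        chi2 = float("nan")
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    background = float(pos.mean())
    return dict(n_ese=len(ese), overlap_fraction=frac,
                background_fraction=background, chi2=float(chi2), p=float(p))


def positional_profile(hexamer_set: set[str], exons: list[tuple[SiteKey, SiteKey]],
                       genome: Genome, window: int = 100) -> pd.DataFrame:
    """Fraction of positions matching a hexamer set around constitutive exons.

    ``exons`` lists (acceptor site, donor site) pairs flanking each exon;
    positions are hexamer start offsets relative to the exon start
    (acceptor boundary), in transcript sense.  Exons shorter than the
    window are skipped.
    """
    offsets = np.arange(-window, window + 1)
    hits = np.zeros(len(offsets))
    n = 0
    for acceptor, donor in exons:
        chrom, strand, _, apos = acceptor
        dpos = donor[3]
        exon_len = abs(dpos - apos)
        if exon_len < window:
            continue
        n += 1
        for i, o in enumerate(offsets):
            if strand == "+":
                h = genome.fetch(chrom, apos + o, apos + o + 6)
            else:
                h = revcomp(genome.fetch(chrom, apos - o - 6, apos - o))
            if len(h) == 6 and h in hexamer_set:
                hits[i] += 1
    frac = hits / n if n else np.full(len(offsets), np.nan)
    return pd.DataFrame(dict(offset=offsets, fraction=frac, n_exons=n))


def constitutive_exons(junctions: pd.DataFrame, annotation: Annotation
                       ) -> list[tuple[SiteKey, SiteKey]]:
    """Internal exons whose flanking sites each have a single partner."""
    partners: dict[SiteKey, set] = {}
    for row in junctions.itertuples(index=False):
        d, a = junction_sites(row.chrom, row.strand, int(row.start), int(row.end))
        partners.setdefault(d, set()).add(a)
        partners.setdefault(a, set()).add(d)
    out = []
    for g in annotation.genes:
        introns = g.introns
        for i in range(len(introns) - 1):
            # exon between intron i and intron i+1 (genomic order)
            k1 = (g.chrom, g.strand, introns[i][0], introns[i][1])
            k2 = (g.chrom, g.strand, introns[i + 1][0], introns[i + 1][1])
            d1, a1 = junction_sites(*k1)
            d2, a2 = junction_sites(*k2)
            # flanking sites of the exon: acceptor of the upstream intron,
            # donor of the downstream intron (in transcription sense)
            if g.strand == "+":
                acc, don = a1, d2
            else:
                acc, don = a2, d1
            if len(partners.get(acc, set())) == 1 and len(partners.get(don, set())) == 1:
                out.append((acc, don))
    return out
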