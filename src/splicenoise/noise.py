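"""Splicing-noise metrics.

Covers the conservation-based analyses: per-offset conservation profiles
around splice sites, conservation labels from the two canonical intronic
bases, reading-frame periodicity of minor splice sites near major
protein-coding sites, per-intron splicing error rates (fraction of reads
from a conserved junction's ends going to unconserved partners), their
correlates (intron length, gene expression) with residual correction,
and polymorphism profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline

from .annotation import (Annotation, SiteKey, junction_sites,
                         site_canonical_bases)
from .config import RunConfig
from .synthetic.conservation import ConservationTrack
from .synthetic.genome import Genome

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- conservation

def _offset_position(site: SiteKey, offset: int) -> int:
    """Forward-genome position at a signed offset from a splice site.

    Positive offsets run into the intron, negative into the exon; offset
    +1 is the first intronic base, -1 the first exonic base.  Offset 0 is
    undefined.
    """
    chrom, strand, typ, pos = site
    if offset == 0:
        raise ValueError("offset 0 is not a base; the axis skips zero")
    intron_at_start = (strand == "+") == (typ == "5")
    if intron_at_start:
        return pos + offset - 1 if offset > 0 else pos + offset
    return pos - offset if offset > 0 else pos - offset - 1


def label_conservation(site: SiteKey, track: ConservationTrack,
                       t_hi: float = 1.5, t_lo: float = 0.5) -> str:
    """'conserved' / 'unconserved' / 'intermediate' from the two canonical bases."""
    chrom = site[0]
    p1, p2 = site_canonical_bases(site)
    if not track.covers(chrom, min(p1, p2), max(p1, p2) + 1):
        logger.warning("site %s outside conservation track; labelled intermediate", site)
        return "intermediate"
    m = (track.score(chrom, p1) + track.score(chrom, p2)) / 2.0
    if m >= t_hi:
        return "conserved"
    if m <= t_lo:
        return "unconserved"
    return "intermediate"


def conservation_profile(sites: list[SiteKey], track: ConservationTrack,
                         window: int = 100) -> pd.DataFrame:
    """Mean conservation score per signed offset over a set of splice sites."""
    offsets = [o for o in range(-window, window + 1) if o != 0]
    sums = np.zeros(len(offsets))
    counts = np.zeros(len(offsets), dtype=np.int64)
    partial = 0
    for site in sites:
        chrom = site[0]
        arr = track.array(chrom)
        complete = True
        for i, o in enumerate(offsets):
            p = _offset_position(site, o)
            if 0 <= p < len(arr):
                sums[i] += arr[p]
                counts[i] += 1
            else:
                complete = False
        partial += int(not complete)
    if partial:
        logger.warning("%d sites had partial track coverage", partial)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(dict(offset=offsets, mean_score=means, n=counts,
                             side=["intronic" if o > 0 else "exonic" for o in offsets]))


def label_junction_sites(junctions: pd.DataFrame, track: ConservationTrack,
                         cfg: RunConfig | None = None) -> dict[SiteKey, str]:
    """Conservation label for every site appearing in a junction table."""
    cfg = cfg or RunConfig()
    labels: dict[SiteKey, str] = {}
    for row in junctions.itertuples(index=False):
        for site in junction_sites(row.chrom, row.strand, int(row.start), int(row.end)):
            if site not in labels:
                labels[site] = label_conservation(site, track,
                                                  cfg.conserved_threshold,
                                                  cfg.unconserved_threshold)
    return labels


# ----------------------------------------------------------------- periodicity

@dataclass
class PeriodicityResult:
    profile: pd.DataFrame
    n_sites: int
    n_minor: int
    n_in_frame: int
    in_frame_fraction: float
    pvalue: float


def _site_dinuc_ok(genome: Genome, site_type: str, strand: str, chrom: str,
                   boundary: int) -> bool:
    """Would a splice site of this type be possible at this boundary?

    Donor sites need sense-GT at the intron start, acceptors sense-AG at
    the intron end; on the minus strand these appear as AC / CT on the
    forward genome.
    """
    seq = genome.seq(chrom)
    if site_type == "5":
        if strand == "+":
            return seq[boundary:boundary + 2] == "GT"
        return seq[boundary - 2:boundary] == "AC"
    if strand == "+":
        return seq[boundary - 2:boundary] == "AG"
    return seq[boundary:boundary + 2] == "CT"


def periodicity_profile(junctions: pd.DataFrame, annotation: Annotation,
                        genome: Genome, side: str = "3",
                        cfg: RunConfig | None = None) -> PeriodicityResult:
    """Minor-splice-site density vs dinucleotide opportunity around major sites.

    For ``side='3'``: among 5' sites with at least ``periodicity_min_coverage``
    reads, at least two 3' partners, a major partner holding at least
    ``periodicity_major_share`` of reads, and both the 5' site and the
    major 3' site annotated in protein-coding sequence, count minor 3'
    sites at each signed offset from the major site and divide by the
    number of AG dinucleotides at that offset.  Offsets -2..+2 are
    excluded (mapping ambiguity).  ``side='5'`` is the mirror analysis
    with GT opportunities.  The in-frame excess of minor sites is tested
    with a one-sided exact binomial test against 1/3.
    """
    cfg = cfg or RunConfig()
    window = cfg.periodicity_window
    anchor_type, minor_type = ("5", "3") if side == "3" else ("3", "5")

    groups: dict[SiteKey, list[tuple[SiteKey, int]]] = {}
    for row in junctions.itertuples(index=False):
        d, a = junction_sites(row.chrom, row.strand, int(row.start), int(row.end))
        anchor, minor = (d, a) if side == "3" else (a, d)
        groups.setdefault(anchor, []).append((minor, int(row.reads)))

    offsets = np.array([o for o in range(-window, window + 1) if abs(o) > 2])
    minor_counts = np.zeros(len(offsets), dtype=np.int64)
    opp_counts = np.zeros(len(offsets), dtype=np.int64)
    minor_offsets_all: list[int] = []
    n_sites = 0
    anchor_set = (annotation.donor_sites if anchor_type == "5"
                  else annotation.acceptor_sites)
    major_set = (annotation.acceptor_sites if minor_type == "3"
                 else annotation.donor_sites)
    for anchor, partners in groups.items():
        total = sum(r for _, r in partners)
        if total < cfg.periodicity_min_coverage or len(partners) < 2:
            continue
        partners = sorted(partners, key=lambda x: -x[1])
        major, major_reads = partners[0]
        if major_reads / total < cfg.periodicity_major_share:
            continue
        if anchor not in anchor_set or annotation.region_of_site(anchor) != "CDS":
            continue
        if major not in major_set or annotation.region_of_site(major) != "CDS":
            continue
        n_sites += 1
        chrom, strand, typ, mpos = major
        # signed offset in transcription direction (downstream positive)
        sign = 1 if strand == "+" else -1
        for minor, _ in partners[1:]:
            o = (minor[3] - mpos) * sign
            if 2 < abs(o) <= window:
                minor_offsets_all.append(int(o))
                minor_counts[np.searchsorted(offsets, o)] += 1
        seq = genome.seq(chrom)
        for i, o in enumerate(offsets):
            b = mpos + o * sign
            if b < 2 or b > len(seq) - 2:
                continue
            if _site_dinuc_ok(genome, minor_type, strand, chrom, int(b)):
                opp_counts[i] += 1

    ratio = np.where(opp_counts > 0, minor_counts / np.maximum(opp_counts, 1), np.nan)
    profile = pd.DataFrame(dict(offset=offsets, minor_sites=minor_counts,
                                opportunities=opp_counts, ratio=ratio,
                                in_frame=(offsets % 3 == 0)))
    n_minor = len(minor_offsets_all)
    n_if = sum(1 for o in minor_offsets_all if o % 3 == 0)
    if n_minor:
        p = stats.binomtest(n_if, n_minor, 1 / 3, alternative="greater").pvalue
        frac = n_if / n_minor
    else:
        logger.warning("no qualifying minor sites for periodicity (%s')", side)
        p, frac = float("nan"), float("nan")
    return PeriodicityResult(profile=profile, n_sites=n_sites, n_minor=n_minor,
                             n_in_frame=n_if, in_frame_fraction=frac,
                             pvalue=float(p))


# ----------------------------------------------------------- error-rate tables

def intron_error_rate(junctions: pd.DataFrame, labels: dict[SiteKey, str],
                      annotation: Annotation, cfg: RunConfig | None = None
                      ) -> tuple[pd.DataFrame, dict]:
    """Per-intron splicing error rate from conservation labels.

    For every annotated junction whose two sites are both conserved, the
    error rate is the fraction of reads involving either end that splice
    to an unconserved partner site.  Reads to intermediate-label partners
    are excluded from numerator and denominator (conservative lower
    bound); a variant including them in the denominator is also reported.
    """
    cfg = cfg or RunConfig()
    by_site: dict[SiteKey, list[int]] = {}
    rows = list(junctions.itertuples(index=False))
    for i, row in enumerate(rows):
        for site in junction_sites(row.chrom, row.strand, int(row.start), int(row.end)):
            by_site.setdefault(site, []).append(i)

    out = []
    tot_err = tot_denom = tot_denom_with_int = 0.0
    for i, row in enumerate(rows):
        key = (row.chrom, row.strand, int(row.start), int(row.end))
        if key not in annotation.introns:
            continue
        d, a = junction_sites(*key)
        if labels.get(d) != "conserved" or labels.get(a) != "conserved":
            continue
        err = cons = inter = 0
        seen = {i}
        for end_site, partner_pick in ((d, "a"), (a, "d")):
            for j in by_site.get(end_site, []):
                if j in seen:
                    continue
                seen.add(j)
                r = rows[j]
                pd_, pa = junction_sites(r.chrom, r.strand, int(r.start), int(r.end))
                partner = pa if partner_pick == "a" else pd_
                lab = labels.get(partner, "intermediate")
                if lab == "unconserved":
                    err += r.reads
                elif lab == "conserved":
                    cons += r.reads
                else:
                    inter += r.reads
        denom = row.reads + cons + err
        if denom == 0:
            continue
        out.append(dict(chrom=row.chrom, strand=row.strand, start=int(row.start),
                        end=int(row.end), length=int(row.end - row.start),
                        reads_conserved=int(row.reads + cons),
                        reads_unconserved=int(err),
                        reads_intermediate=int(inter),
                        error_rate=err / denom))
        tot_err += err
        tot_denom += denom
        tot_denom_with_int += denom + inter
    table = pd.DataFrame(out)
    summary = dict(
        n_introns=len(table),
        global_error_rate=(tot_err / tot_denom) if tot_denom else float("nan"),
        global_error_rate_with_intermediate=(tot_err / tot_denom_with_int
                                             if tot_denom_with_int else float("nan")),
        mean_intron_error_rate=(float(table["error_rate"].mean())
                                if len(table) else float("nan")),
        conserved_threshold=cfg.conserved_threshold,
        unconserved_threshold=cfg.unconserved_threshold,
    )
    return table, summary


def per_gene_missplice(rate: float, n_introns: int) -> float:
    """Expected fraction of transcripts with >= 1 splicing error.

    With independent per-intron error probability ``rate`` over
    ``n_introns`` splicing reactions: 1 - (1 - rate)^n.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    return 1.0 - (1.0 - rate) ** n_introns


# ------------------------------------------------------------------ correlates

def expression_level(exons: list[tuple[int, int]],
                     alignments_by_sample: list[np.ndarray]) -> float:
    """Reads per exonic base, maximized across samples.

    ``alignments_by_sample`` holds, per sample, the start positions of
    contiguously mapped reads (same chromosome as the gene); a read counts
    toward the gene when its start falls inside an exon.
    """
    exonic = sum(e - s for s, e in exons)
    if exonic <= 0:
        raise ValueError("gene has zero exonic length")
    best = 0.0
    for starts in alignments_by_sample:
        starts = np.asarray(starts)
        n = 0
        for s, e in exons:
            n += int(((starts >= s) & (starts < e)).sum())
        best = max(best, n / exonic)
    return best


def bin_and_trend(table: pd.DataFrame, covariate: str, rate_col: str = "error_rate",
                  n_bins: int = 100, log_covariate: bool = True
                  ) -> tuple[pd.DataFrame, dict]:
    """Equal-count binning of per-intron error rates against a covariate.

    Returns the binned means with a cubic smoothing-spline fit (GCV) and
    Spearman's rho over the bin means as the trend statistic.  Ties at
    bin edges are broken deterministically by intron coordinates.
    """
    if len(table) < n_bins:
        raise ValueError(f"need at least {n_bins} introns, have {len(table)}")
    sort_cols = [covariate] + [c for c in ("chrom", "start", "end") if c in table]
    df = table.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    bins = np.array_split(np.arange(len(df)), n_bins)
    x = np.array([np.log10(df[covariate].iloc[b].mean()) if log_covariate
                  else df[covariate].iloc[b].mean() for b in bins])
    y = np.array([df[rate_col].iloc[b].mean() for b in bins])
    sizes = np.array([len(b) for b in bins])
    rho, pval = stats.spearmanr(x, y)
    spline_y = np.full_like(y, np.nan)
    # collapse tied bin means: the spline needs strictly increasing x
    ux, inv = np.unique(x, return_inverse=True)
    if len(ux) > 5:
        uy = np.bincount(inv, weights=y) / np.bincount(inv)
        spl = make_smoothing_spline(ux, uy)
        spline_y = spl(x)
    binned = pd.DataFrame({f"mean_{covariate}": x, "mean_error_rate": y,
                           "n": sizes, "spline": spline_y})
    return binned, dict(spearman_rho=float(rho), spearman_p=float(pval),
                        n_bins=n_bins, covariate=covariate)


def residual_correction(table: pd.DataFrame, covariate_a: str, covariate_b: str,
                        rate_col: str = "error_rate", n_bins: int = 100
                        ) -> dict:
    """Association of error rate with B after removing a linear effect of A.

    The error rate is regressed on log10(A); residuals are re-binned
    against B and the Spearman trend of the binned residual means is
    reported next to the uncorrected association.
    """
    for cov in (covariate_a, covariate_b):
        if table[cov].nunique() <= 1:
            raise ValueError(f"covariate {cov} is constant")
    df = table.copy()
    xa = np.log10(df[covariate_a].astype(float))
    slope, intercept = np.polyfit(xa, df[rate_col], 1)
    df["_resid"] = df[rate_col] - (slope * xa + intercept)
    _, raw = bin_and_trend(df, covariate_b, rate_col=rate_col, n_bins=n_bins)
    _, corr = bin_and_trend(df, covariate_b, rate_col="_resid", n_bins=n_bins)
    return dict(raw_rho=raw["spearman_rho"], raw_p=raw["spearman_p"],
                corrected_rho=corr["spearman_rho"], corrected_p=corr["spearman_p"],
                slope_on_a=float(slope), residual_mean=float(df["_resid"].mean()))


# ---------------------------------------------------------------- polymorphism

def polymorphism_profile(sites: list[SiteKey],
                         variant_positions: dict[str, np.ndarray],
                         window: int = 30) -> pd.DataFrame:
    """Fraction of sites polymorphic at each signed offset."""
    offsets = [o for o in range(-window, window + 1) if o != 0]
    variant_sets = {c: set(map(int, v)) for c, v in variant_positions.items()}
    hits = np.zeros(len(offsets))
    n = len(sites)
    for site in sites:
        vs = variant_sets.get(site[0], set())
        for i, o in enumerate(offsets):
            if _offset_position(site, o) in vs:
                hits[i] += 1
    frac = hits / n if n else np.full(len(offsets), np.nan)
    return pd.DataFrame(dict(offset=offsets, fraction=frac, n_sites=n))
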