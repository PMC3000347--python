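"""Junction catalogue: dinucleotide filtering, FDR, classification, usage.

The control-dinucleotide FDR follows the logic of replacing the acceptor
consensus AG with its complement TC: a junction consistent (under any
placement of its equivalence class) with GT-AG or GC-AG is canonical; one
consistent only with GT-TC or GC-TC is a control.  Assuming every control
is a false positive, FDR = n_control / n_canonical.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .annotation import Annotation, junction_sites
from .config import RunConfig
from .mapper import JunctionCandidate, classify_dinucs, shift_equivalence
from .synthetic.genome import Genome

logger = logging.getLogger(__name__)


def attach_dinuc_class(junctions: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    """Add dinucleotide class and placement count from the genome sequence.

    Used for junction tables built without the mapper (e.g. directly from
    simulated counts); tables from the mapper already carry these columns.
    """
    classes, n_plac = [], []
    for row in junctions.itertuples(index=False):
        c = JunctionCandidate(row.chrom, row.strand, int(row.start),
                              int(row.end), "", 0, 0)
        shift_equivalence(c, genome)
        classes.append(classify_dinucs(c.dinucs))
        n_plac.append(len(c.placements))
    out = junctions.copy()
    out["dinuc_class"] = classes
    out["n_placements"] = n_plac
    return out


def filter_canonical(junctions: pd.DataFrame
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split a junction table into (canonical, control, other) sets."""
    if "dinuc_class" not in junctions:
        raise ValueError("junction table lacks dinuc_class; run the mapper "
                         "or attach_dinuc_class first")
    canonical = junctions[junctions["dinuc_class"].isin(["GT-AG", "GC-AG"])]
    control = junctions[junctions["dinuc_class"] == "control"]
    other = junctions[junctions["dinuc_class"] == "other"]
    return canonical, control, other


def estimate_fdr(n_canonical: int, n_control: int) -> float:
    """FDR estimate assuming every control-dinucleotide junction is false."""
    if n_canonical <= 0:
        raise ValueError("FDR undefined: no canonical junctions")
    return n_control / n_canonical


ANNOTATION_CLASSES = ["known_junction", "both_ends_known_new_pairing",
                      "new_3ss", "new_5ss", "both_new"]


def classify_junctions(junctions: pd.DataFrame, annotation: Annotation,
                       cfg: RunConfig | None = None
                       ) -> tuple[pd.DataFrame, dict]:
    """Five-way classification of junctions against annotated gene models.

    Classes: annotated junction; both sites annotated but never paired;
    annotated 5' site only (novel 3' site); annotated 3' only (novel 5');
    neither.  Also records per-end nearest-annotated distances and
    summary fractions (share of junctions, and of junction-spanning
    reads, that are unannotated).
    """
    cfg = cfg or RunConfig()
    if not annotation.introns:
        logger.warning("empty annotation: all junctions classed both_new")
    rows = []
    for row in junctions.itertuples(index=False):
        key = (row.chrom, row.strand, int(row.start), int(row.end))
        d, a = junction_sites(*key)
        d_ann = d in annotation.donor_sites
        a_ann = a in annotation.acceptor_sites
        if key in annotation.introns:
            cls = "known_junction"
        elif d_ann and a_ann:
            cls = "both_ends_known_new_pairing"
        elif d_ann:
            cls = "new_3ss"
        elif a_ann:
            cls = "new_5ss"
        else:
            cls = "both_new"
        rows.append(dict(annotation_class=cls,
                         donor_annotated=d_ann, acceptor_annotated=a_ann,
                         donor_dist=annotation.nearest_site_distance(d),
                         acceptor_dist=annotation.nearest_site_distance(a)))
    out = pd.concat([junctions.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
    unann = out["annotation_class"] != "known_junction"
    total_reads = out["reads"].sum()
    summary = dict(
        n_junctions=len(out),
        n_unannotated=int(unann.sum()),
        fraction_unannotated=float(unann.mean()) if len(out) else float("nan"),
        fraction_reads_unannotated=(float(out.loc[unann, "reads"].sum() / total_reads)
                                    if total_reads else float("nan")),
        class_counts=out["annotation_class"].value_counts().to_dict(),
        near_annotated_bp=cfg.near_annotated_bp,
    )
    return out, summary


def splice_site_usage(junctions: pd.DataFrame, min_coverage: int = 50,
                      annotation: Annotation | None = None
                      ) -> tuple[pd.DataFrame, dict]:
    """Per-site usage: partner count and major-form fraction.

    Sites covered by at least ``min_coverage`` reads qualify; the major
    form is the partner junction with the most reads.
    """
    site_rows = []
    for row in junctions.itertuples(index=False):
        d, a = junction_sites(row.chrom, row.strand, int(row.start), int(row.end))
        site_rows.append(dict(site=d, type="5", reads=int(row.reads)))
        site_rows.append(dict(site=a, type="3", reads=int(row.reads)))
    if not site_rows:
        logger.warning("no junctions for splice-site usage")
        return pd.DataFrame(), {}
    df = pd.DataFrame(site_rows)
    agg = df.groupby("site").agg(total=("reads", "sum"),
                                 partners=("reads", "size"),
                                 major=("reads", "max")).reset_index()
    agg = agg[agg["total"] >= min_coverage].copy()
    if not len(agg):
        logger.warning("no splice site reaches coverage %d", min_coverage)
        return pd.DataFrame(), {}
    agg["major_fraction"] = agg["major"] / agg["total"]
    agg["type"] = [s[2] for s in agg["site"]]
    if annotation is not None:
        agg["region"] = [annotation.region_of_site(s) for s in agg["site"]]
        agg["annotated"] = [annotation.is_annotated_site(s) for s in agg["site"]]
    summary = dict(
        n_sites=len(agg),
        mean_partners=float(agg["partners"].mean()),
        mean_major_fraction=float(agg["major_fraction"].mean()),
        min_coverage=min_coverage,
    )
    if annotation is not None:
        for typ in ("5", "3"):
            for region in ("CDS", "UTR"):
                sel = agg[(agg["type"] == typ) & (agg["region"] == region)]
                if len(sel):
                    summary[f"mean_partners_{typ}ss_{region}"] = float(sel["partners"].mean())
    return agg, summary


def saturation_curve(assignments: pd.DataFrame, junctions: pd.DataFrame,
                     depth_grid, n_reps: int, seed: int,
                     unannotated_only: bool = True) -> pd.DataFrame:
    """Junctions discovered as a function of subsampled read depth.

    Reads are subsampled without replacement; at each depth the mean
    number of (by default unannotated) junctions covered by at least one
    sampled read is reported over ``n_reps`` replicates.
    """
    rng = np.random.default_rng(seed)
    read_ids = assignments["read_idx"].unique()
    n = len(read_ids)
    if unannotated_only:
        if "annotation_class" not in junctions:
            raise ValueError("junction table not classified; run classify_junctions")
        eligible = set(np.nonzero((junctions["annotation_class"]
                                   != "known_junction").to_numpy())[0])
    else:
        eligible = set(range(len(junctions)))
    by_read = assignments.groupby("read_idx")["junction_idx"].apply(list)
    rows = []
    for depth in depth_grid:
        m = int(min(depth, n))
        if depth > n:
            logger.warning("saturation depth %d exceeds %d reads; truncated", depth, n)
        vals = []
        for _ in range(n_reps):
            if m == 0:
                vals.append(0)
                continue
            sample = rng.choice(read_ids, size=m, replace=False)
            seen: set[int] = set()
            for r in sample:
                seen.update(by_read[r])
            vals.append(len(seen & eligible))
        rows.append(dict(depth=m, mean_junctions=float(np.mean(vals)),
                         sd=float(np.std(vals))))
    return pd.DataFrame(rows)
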