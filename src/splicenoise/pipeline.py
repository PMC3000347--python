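"""End-to-end pipeline: simulate -> map -> catalogue -> noise metrics -> motifs.

Each stage reads the previous stage's outputs from the run directory,
logs one structured line with its input/output counts, and contributes
its headline numbers to the run report.  A single run seed fans out to
per-stage seeds so stages are individually reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import catalog, io, motifs, noise
from .annotation import Annotation
from .config import RunConfig, SimConfig, derive_seed
from .mapper import build_index, discover_junctions
from .synthetic import (simulate_artifact_reads, simulate_dataset,
                        simulate_junction_reads, simulate_reads)
from .synthetic.variants import write_variant_bed

logger = logging.getLogger(__name__)

PRESETS: dict[str, dict] = {
    "tiny": dict(n_genes=8, intron_log_mean=5.2, intron_log_sigma=0.5,
                 depth=40.0, sequencing_error_rate=0.0),
    "default": dict(n_genes=100),
    "confounded-expression": dict(n_genes=400, per_intron_error_rate=-0.011,
                                  error_length_slope=0.007,
                                  expression_length_coupling=1.5),
    "frame-biased": dict(n_genes=100, frame_bias=0.5),
    "null": dict(n_genes=50, per_intron_error_rate=0.0, frame_bias=1.0),
}


def make_fixture(preset: str, seed: int = 0, **overrides) -> SimConfig:
    """A SimConfig for a named scenario preset.

    Presets: ``tiny`` (mapper-oracle tractable), ``default``,
    ``confounded-expression`` (error rate driven by intron length,
    expression anti-correlated with length), ``frame-biased``
    (NMD survival 0.5 for frame-disrupting errors), ``null`` (no
    splicing errors, no frame bias).
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    kw = dict(PRESETS[preset])
    kw.update(overrides)
    return SimConfig(seed=seed, **kw)


@dataclass
class PipelineResult:
    report: dict
    outdir: Path


def _stage_log(stage: str, **counts) -> None:
    logger.info("stage=%s %s", stage,
                " ".join(f"{k}={v}" for k, v in counts.items()))


def run_pipeline(sim_config: SimConfig, run_config: RunConfig | None = None,
                 outdir: str | Path = "splicenoise_run",
                 n_junction_reads: int = 100_000,
                 n_contiguous_reads: int = 0,
                 stages: list[str] | None = None,
                 write_outputs: bool = True) -> PipelineResult:
    """Run the pipeline and return the run report.

    ``stages`` defaults to all of simulate, map, junctions, classify,
    periodicity, errors, motifs; later stages require earlier ones within
    the same call.
    """
    cfg = run_config or RunConfig()
    stages = stages or ["simulate", "map", "junctions", "classify",
                        "periodicity", "errors", "motifs"]
    out = io.ensure_dir(outdir)
    seed = sim_config.seed
    report: dict = {"seed": seed, "sim_config": json.loads(sim_config.to_json()),
                    "run_config": cfg.asdict(), "stages": stages}

    # ---------------------------------------------------------------- simulate
    data = simulate_dataset(sim_config)
    ann = Annotation(genes=data.truth.genes)
    reads, counts = simulate_junction_reads(
        data.genome, data.truth, sim_config, derive_seed(seed, "reads"),
        total_reads=n_junction_reads)
    if n_contiguous_reads:
        reads = reads + simulate_reads(data.genome, data.truth, sim_config,
                                       derive_seed(seed, "contig"),
                                       n_reads=n_contiguous_reads)
    if sim_config.n_artifact_reads:
        reads = reads + simulate_artifact_reads(data.genome, sim_config,
                                                derive_seed(seed, "artifacts"))
    if write_outputs:
        io.write_fasta(data.genome, out / "genome.fa")
        io.write_gtf(data.truth.genes, out / "genes.gtf")
        io.write_bed12_genes(data.truth.genes, out / "genes.bed12")
        data.track.to_bedgraph(out / "conservation.bedgraph")
        write_variant_bed(data.variant_positions, out / "variants.bed")
        io.write_fastq(reads, out / "reads.fastq")
        data.truth.introns.to_csv(out / "truth_introns.tsv", sep="\t", index=False)
        counts.to_csv(out / "truth_junction_counts.tsv", sep="\t", index=False)
    _stage_log("simulate", genes=len(data.truth.genes),
               introns=len(data.truth.introns), reads=len(reads))
    report["simulate"] = dict(n_genes=len(data.truth.genes),
                              n_introns=len(data.truth.introns),
                              n_reads=len(reads))
    if "map" not in stages:
        return PipelineResult(report, out)

    # --------------------------------------------------------------------- map
    index = build_index(data.genome, cfg.seed_length)
    junctions, assignments, stats = discover_junctions(reads, data.genome, index, cfg)
    if write_outputs:
        io.write_junctions_tsv(junctions, out / "junctions.tsv")
        io.write_junctions_bed12(junctions, out / "junctions.bed12")
    _stage_log("map", **stats)
    report["map"] = stats
    if "junctions" not in stages:
        return PipelineResult(report, out)

    # ----------------------------------------------------- junction catalogue
    canonical, control, other = catalog.filter_canonical(junctions)
    fdr = catalog.estimate_fdr(len(canonical), len(control)) if len(canonical) else float("nan")
    report["junctions"] = dict(n_total=len(junctions), n_canonical=len(canonical),
                               n_control=len(control), n_other=len(other), fdr=fdr)
    _stage_log("junctions", **report["junctions"])

    classified, class_summary = catalog.classify_junctions(canonical, ann, cfg)
    usage, usage_summary = catalog.splice_site_usage(
        classified, cfg.usage_min_coverage, ann)
    if write_outputs:
        io.write_junctions_tsv(classified, out / "junctions_classified.tsv")
        if len(usage):
            usage.assign(site=usage["site"].astype(str)).to_csv(
                out / "splice_site_usage.tsv", sep="\t", index=False)
    report["classify"] = class_summary
    report["usage"] = usage_summary
    _stage_log("classify", **{k: v for k, v in class_summary.items()
                              if not isinstance(v, dict)})

    if "periodicity" in stages:
        for side in ("3", "5"):
            res = noise.periodicity_profile(classified, ann, data.genome, side, cfg)
            report[f"periodicity_{side}ss"] = dict(
                n_sites=res.n_sites, n_minor=res.n_minor,
                in_frame_fraction=res.in_frame_fraction, pvalue=res.pvalue)
            if write_outputs:
                res.profile.to_csv(out / f"periodicity_{side}ss.tsv",
                                   sep="\t", index=False)
            _stage_log("periodicity", side=side, **report[f"periodicity_{side}ss"])

    if "errors" in stages:
        labels = noise.label_junction_sites(classified, data.track, cfg)
        table, err_summary = noise.intron_error_rate(classified, labels, ann, cfg)
        report["error_rate"] = err_summary
        if write_outputs and len(table):
            table.to_csv(out / "intron_error_rates.tsv", sep="\t", index=False)
        if len(table) >= cfg.n_bins:
            binned, trend = noise.bin_and_trend(table, "length", n_bins=cfg.n_bins)
            report["length_trend"] = trend
            if write_outputs:
                binned.to_csv(out / "error_rate_by_length.tsv", sep="\t", index=False)
        _stage_log("errors", **err_summary)

    if "motifs" in stages:
        labels = noise.label_junction_sites(classified, data.track, cfg)
        try:
            noise_sites, decoys = motifs.select_noise_and_decoy(
                classified, labels, ann, data.genome, cfg)
        except ValueError as exc:
            logger.warning("motif stage skipped: %s", exc)
            report["motifs"] = dict(error=str(exc))
        else:
            mot = {}
            for typ in ("5", "3"):
                sites = [ns.site for ns in noise_sites if ns.site[2] == typ]
                dsites = [(d.noise.site[0], d.noise.site[1], typ, d.position)
                          for d in decoys if d.noise.site[2] == typ]
                if not sites or not dsites:
                    continue
                ex_n, in_n = motifs.extract_flanks(sites, data.genome, cfg)
                ex_d, in_d = motifs.extract_flanks(dsites, data.genome, cfg)
                for region, sn, sd in (("exonic", ex_n, ex_d), ("intronic", in_n, in_d)):
                    enr = motifs.enrichment_test(motifs.hexamer_counts(sn),
                                                 motifs.hexamer_counts(sd),
                                                 cfg.motif_alpha)
                    mot[f"{typ}ss_{region}"] = int(enr["significant"].sum())
                    if write_outputs:
                        enr.to_csv(out / f"hexamer_enrichment_{typ}ss_{region}.tsv",
                                   sep="\t", index=False)
            report["motifs"] = dict(n_noise_sites=len(noise_sites),
                                    n_decoys=len(decoys),
                                    significant_hexamers=mot)
            _stage_log("motifs", n_noise=len(noise_sites), **mot)

    if write_outputs:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return PipelineResult(report, out)
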