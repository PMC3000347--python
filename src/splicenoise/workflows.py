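"""Canned end-to-end experiments.

These wrap the full pipeline into single calls that return the headline
quantities — used both programmatically and by reproduction scripts.
"""

from __future__ import annotations

import logging
import math

from .annotation import Annotation
from .config import RunConfig, SimConfig, derive_seed
from .mapper import build_index, discover_junctions
from .catalog import filter_canonical
from .noise import intron_error_rate, label_junction_sites
from .synthetic import simulate_dataset, simulate_junction_reads

logger = logging.getLogger(__name__)


def recover_error_rate(seed: int, n_genes: int = 200,
                       total_reads: int = 2_000_000,
                       per_intron_error_rate: float = 0.007,
                       run_config: RunConfig | None = None) -> dict:
    """Recover the per-intron splicing error rate from raw reads.

    Simulates a genome with the given per-intron cryptic-splicing
    probability, generates ``total_reads`` junction-spanning reads, runs
    split-read junction discovery, labels splice-site conservation, and
    computes the global conserved-to-unconserved read fraction.  Returns
    the recovered rate, its binomial standard error at the generator
    value, and bookkeeping counts.
    """
    cfg = SimConfig(n_genes=n_genes, per_intron_error_rate=per_intron_error_rate,
                    seed=seed)
    rcfg = run_config or RunConfig()
    data = simulate_dataset(cfg)
    ids, mat, counts = simulate_junction_reads(
        data.genome, data.truth, cfg, derive_seed(seed, "reads"),
        total_reads=total_reads, return_matrix=True)
    n_reads = len(ids)
    logger.info("simulated %d junction-spanning reads", n_reads)

    def read_iter():
        for i, rid in enumerate(ids):
            yield rid, mat[i].tobytes().decode("ascii")

    index = build_index(data.genome, rcfg.seed_length)
    junctions, _, stats = discover_junctions(read_iter(), data.genome, index, rcfg)
    canonical, control, other = filter_canonical(junctions)
    ann = Annotation(genes=data.truth.genes)
    labels = label_junction_sites(canonical, data.track, rcfg)
    _, summary = intron_error_rate(canonical, labels, ann, rcfg)
    rate = summary["global_error_rate"]
    se = math.sqrt(per_intron_error_rate * (1 - per_intron_error_rate) / n_reads)
    return dict(recovered_rate=rate,
                generator_rate=per_intron_error_rate,
                binomial_se=se,
                within_3se=abs(rate - per_intron_error_rate) <= 3 * se,
                n_reads=n_reads,
                n_junctions=len(junctions),
                n_canonical=len(canonical),
                mapper_stats=stats)
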