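"""Shared fixtures: small synthetic datasets reused across test modules."""

from __future__ import annotations

import pytest

from splicenoise.annotation import Annotation
from splicenoise.config import SimConfig
from splicenoise.pipeline import make_fixture
from splicenoise.synthetic import simulate_dataset, simulate_junction_counts


@pytest.fixture(scope="session")
def tiny_data():
    """Mapper-oracle-tractable dataset: 8 genes, short introns, no seq errors."""
    return simulate_dataset(make_fixture("tiny", seed=11))


@pytest.fixture(scope="session")
def default_data():
    """Medium dataset (100 genes) for catalogue / noise-metric tests."""
    return simulate_dataset(SimConfig(n_genes=100, seed=5))


@pytest.fixture(scope="session")
def default_counts(default_data):
    """Junction read counts at 300k junction-spanning reads."""
    d = default_data
    return simulate_junction_counts(d.genome, d.truth, d.config, seed=21,
                                    total_reads=300_000)


@pytest.fixture(scope="session")
def default_junctions(default_counts):
    """Plain junction table (chrom/strand/start/end/reads) from the counts."""
    return default_counts[["chrom", "strand", "start", "end", "reads"]].copy()


@pytest.fixture(scope="session")
def default_annotation(default_data):
    return Annotation(genes=default_data.truth.genes)
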