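"""Shared fixtures: one small synthetic study per session plus tiny files."""

from __future__ import annotations

import numpy as np
import pytest

import methylome_kit as mk


SMALL_CONFIG = mk.SimulationConfig(
    seed=42, n_contigs=2, contig_length=120_000, n_genes=40,
    frac_methylated_genes=0.25,
)


@pytest.fixture(scope="session")
def small_study():
    """A compact end-to-end study reused across the suite."""
    return mk.simulate_study(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_calls(small_study):
    counts = small_study.counts
    return mk.call_sites(
        counts[counts["context"] == "CpG"], error_rate=0.01, min_reads=2
    )


@pytest.fixture(scope="session")
def small_gene_table(small_study, small_calls):
    assign = mk.assign_sites(
        small_calls, small_study.genes, small_study.contig_lengths
    )
    return mk.compute_ratios(assign, small_calls, genes=small_study.genes)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
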