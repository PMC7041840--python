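"""Shared fixtures: small seeded synthetic datasets reused across modules."""

from __future__ import annotations

import pytest

from methexpr import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 20-gene paired dataset with 2 coupled candidate genes."""
    cfg = SimulationConfig(
        seed=11,
        n_genes=20,
        chrom_length=300_000,
        coverage_mean=10.0,
        n_up_spiked=2,
        n_down_spiked=2,
        n_candidate_spiked=2,
    )
    data = simulate_dataset(cfg)
    data["config"] = cfg
    return data


@pytest.fixture(scope="session")
def recovery_dataset():
    """The parameter-recovery design: 200 genes, 3 vs 3 replicates,
    10 candidate genes with 8-fold expression and 0.4-fold promoter
    demethylation at 50x coverage."""
    cfg = SimulationConfig(
        seed=20200225,
        n_genes=200,
        chrom_length=2_400_000,
        coverage_mean=50.0,
        nb_mean=100.0,
        n_up_spiked=0,
        n_down_spiked=0,
        n_candidate_spiked=10,
        expr_effect=8.0,
        demeth_effect=0.4,
    )
    data = simulate_dataset(cfg)
    data["config"] = cfg
    return data
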