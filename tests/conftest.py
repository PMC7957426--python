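"""Shared fixtures: one small config for unit tests and the session-scoped
study runs (simulate -> align -> call / profile) reused across test modules."""

from __future__ import annotations

import pytest

from bsribo.config import SimulationConfig
from bsribo.sim.reference import make_reference
from bsribo.study import (
    neutral_study_config,
    run_bs_study,
    run_ribo_study,
    stall_dwell,
    study_config,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale config for fast unit tests."""
    return SimulationConfig(
        seed=123,
        n_mrna=6,
        cds_len_range=(60, 90),
        n_trna=6,
        n_rrna=2,
        rrna_len=300,
        bs_depth=15.0,
        ribo_depth=20_000,
        rna_depth=40_000,
        n_codon_biased=2,
    )


@pytest.fixture(scope="session")
def small_ref(small_config):
    return make_reference(small_config)


@pytest.fixture(scope="session")
def bs_study():
    """Full planted-truth bisulfite study: 100 NSUN-dependent sites at ~50x
    coverage, 99% deamination, three replicates per genotype."""
    return run_bs_study(seed=7)


@pytest.fixture(scope="session")
def noise_bs_study():
    """Site-free symmetric-noise bisulfite study (threshold-sweep calibration)."""
    cfg = study_config(11, n_mrna=10, n_trna=8, n_rrna=2)
    return run_bs_study(seed=11, site_specs=[], config=cfg)


@pytest.fixture(scope="session")
def ribo_uniform_study():
    """Uniform-dwell profiling study on the large neutrality reference."""
    return run_ribo_study(seed=5, config=neutral_study_config(5), n_reps=3)


@pytest.fixture(scope="session")
def ribo_stall_study():
    """Stall study: 2.5x UUG dwell planted in the knockout under heat, 3v3."""
    return run_ribo_study(seed=3, dwell_multipliers=stall_dwell(), n_reps=3)
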