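"""Shared fixtures: small handcrafted annotation records and simulated
cohorts at the sizes the different test tiers need."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from coordx.genome_io import GeneModel
from coordx.synthetic_data import SimConfig, simulate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(20140819)


@pytest.fixture()
def three_genes() -> list[GeneModel]:
    """Three valid handcrafted gene models (two strands, multi-exon)."""
    return [
        GeneModel("NM_001", "ALPHA", "chr1", "+", 1000, 6000, 1200, 5400, 3,
                  (1000, 2500, 5000), (1500, 3000, 6000)),
        GeneModel("NM_002", "BETA", "chr1", "-", 9000, 12000, 9100, 11800, 2,
                  (9000, 11000), (10000, 12000)),
        GeneModel("NM_003", "GAMMA", "chr2", "+", 100, 1100, 100, 1100, 1,
                  (100,), (1100,)),
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """2,000-gene default-calibration cohort for unit-level checks."""
    return simulate_cohort(SimConfig(n_genes=2000, seed=11))


@pytest.fixture(scope="session")
def cohort20k():
    """Full-size (20,000-gene) default mouse cohort, fixed seed."""
    return simulate_cohort(SimConfig(n_genes=20000, seed=7))
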