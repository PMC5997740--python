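"""Shared fixtures: small chromosome tables and desk-scale scenario runs.

The desk-scale experiments (32x32 lattice, 3-pair toy table, 20,000 steps,
5 replicates) are session-scoped because several behavioural checks read
different aspects of the same scenario.
"""

import numpy as np
import pytest

import pennaxy as px
from pennaxy.genome import ChromosomeSpec, ChromosomeTable

DESK_BASE_SEED = 1


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_table():
    """One sex pair of 4 loci with basic length 4 (one locus per year)."""
    return ChromosomeTable(
        [ChromosomeSpec("XY", 4, 0.0, 0.0, is_sex_pair=True)], basic_length=4)


@pytest.fixture
def small_table():
    """Three pairs of unequal length with basic length 4."""
    return ChromosomeTable(
        [
            ChromosomeSpec("A1", 8, 0.1, 0.5),
            ChromosomeSpec("A2", 4, 0.1, 0.5),
            ChromosomeSpec("XY", 4, 0.1, 0.5, is_sex_pair=True),
        ],
        basic_length=4)


def desk_experiment(preset: str) -> px.ExperimentResult:
    cfg = px.preset_config(preset, seed=DESK_BASE_SEED)
    return px.run_replicates(cfg)


@pytest.fixture(scope="session")
def ru_experiment():
    return desk_experiment("DESK-RU")


@pytest.fixture(scope="session")
def nu_experiment():
    return desk_experiment("DESK-NU")


@pytest.fixture(scope="session")
def nf_experiment():
    return desk_experiment("DESK-NF")


@pytest.fixture(scope="session")
def ef_experiment():
    return desk_experiment("DESK-EF")


@pytest.fixture(scope="session")
def eu_experiment():
    return desk_experiment("DESK-EU")
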