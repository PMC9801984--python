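import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", message=".*time_units.*")

from declinesim.datasets import DataTypeSpec, SamplingScheme, assemble_dataset, draw_samples
from declinesim.demography import (
    DemographicScenario,
    SizeTrajectory,
    life_history,
)
from declinesim.pipeline import simulate_tables


@pytest.fixture(scope="session")
def tiny_constant_sim():
    """Stable Ne=200 simulation, 2 x 1.5 Mb chromosomes, all five checkpoints."""
    scenario = DemographicScenario(
        life_history("G1"), SizeTrajectory(Ne_H=200)
    )
    pedigree, tables = simulate_tables(
        scenario, seed=101, n_chromosomes=2, chromosome_length=1_500_000, n_record=60
    )
    return scenario, pedigree, tables


@pytest.fixture(scope="session")
def tiny_decline_sim():
    """Declining Ne=200 (lambda=0.95 from 30 ybp) with contemporary+historic checkpoints."""
    scenario = DemographicScenario(
        life_history("G1"), SizeTrajectory(Ne_H=200, lambda_=0.95, T_dec=30)
    )
    pedigree, tables = simulate_tables(
        scenario, seed=202, n_chromosomes=2, chromosome_length=1_500_000, n_record=60
    )
    return scenario, pedigree, tables


@pytest.fixture(scope="session")
def tiny_dataset(tiny_constant_sim):
    """Two-sample WGS dataset of 20 individuals from the stable simulation."""
    scenario, pedigree, tables = tiny_constant_sim
    rng = np.random.default_rng(7)
    scheme = SamplingScheme("two_sample", 20)
    chosen = draw_samples(pedigree.checkpoints, scheme, rng)
    return assemble_dataset(
        tables, chosen, scheme, DataTypeSpec(kind="WGS", genome_length=3_000_000), rng
    )
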