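import logging

import pytest

from pirnakit.aligner import GenomeIndex
from pirnakit.io_formats import configure_logging
from pirnakit.synthetic_data import SimConfig, SimulationTruth, build_genome

configure_logging(logging.WARNING)


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def model(sim_config):
    """One default miniature genome shared across the suite."""
    return build_genome(sim_config, seed=101)


@pytest.fixture(scope="session")
def genome_index(model) -> GenomeIndex:
    return GenomeIndex(model.chromosomes)


@pytest.fixture(scope="session")
def null_truth() -> SimulationTruth:
    return SimulationTruth.null(seed=101)
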