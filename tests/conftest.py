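import numpy as np
import pytest

from pmdkit import SimulationConfig, call_pmds, simulate_methylome


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    """Default-condition synthetic genome, fixed seed."""
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def methylome_wt(sim_config):
    return simulate_methylome(sim_config, "WT")


@pytest.fixture(scope="session")
def methylome_ko(sim_config):
    return simulate_methylome(sim_config, "KO")


@pytest.fixture(scope="session")
def called_domains(sim_config, methylome_wt):
    records, truth = methylome_wt
    return call_pmds(records, sim_config.layout, truth.exclusions, seed=1)


def per_base_mask(intervals, chrom, length):
    """Boolean occupancy array oracle for interval algebra."""
    mask = np.zeros(length, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            mask[iv.start : iv.end] = True
    return mask
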