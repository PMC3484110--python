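import numpy as np
import pytest

from erkpop import population as pop
from erkpop.cascade import KineticParameters, ProteinTotals
from erkpop.ras_input import build_dose_schedule


@pytest.fixture(scope="session")
def schedule():
    return build_dose_schedule()


@pytest.fixture(scope="session")
def totals():
    return ProteinTotals()


@pytest.fixture(scope="session")
def nf_params():
    return KineticParameters.for_topology("NF")


@pytest.fixture(scope="session")
def pf_params():
    return KineticParameters.for_topology("PF")


def _noisy_population(topology, n_cells, seed):
    resp = pop.simulate_population(topology, n_cells, seed=seed)
    return pop.add_measurement_noise(resp, seed=seed)


@pytest.fixture(scope="session")
def nf_population():
    """NF population, 300 cells, full dose x time grid, noise added."""
    return _noisy_population("NF", 300, seed=101)


@pytest.fixture(scope="session")
def pf_population():
    """PF population, 300 cells, full dose x time grid, noise added."""
    return _noisy_population("PF", 300, seed=101)
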