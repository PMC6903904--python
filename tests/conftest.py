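"""Shared fixtures: networks, assembled systems, noiseless reference data."""

from __future__ import annotations

import numpy as np
import pytest

from mitoflux.flux_fitting import observations_from_timecourse
from mitoflux.isotopomer_model import (
    assemble_mass_isotopomer_odes,
    build_default_network,
    simulate_labeling,
)
from mitoflux.synthetic_data import (
    AcetateInput,
    AcquisitionParams,
    TruthRecord,
    generate_saturation_transfer_dataset,
)
from mitoflux.toy_networks import toy_condensation_cycle


@pytest.fixture(scope="session")
def default_network():
    return build_default_network()


@pytest.fixture(scope="session")
def glu_system(default_network):
    return assemble_mass_isotopomer_odes(default_network)


@pytest.fixture(scope="session")
def acetate():
    return AcetateInput()


@pytest.fixture(scope="session")
def t_grid():
    return np.linspace(0.0, 600.0, 13)


@pytest.fixture(scope="session")
def noiseless_timecourse(glu_system, acetate, t_grid):
    return simulate_labeling(glu_system, input_fn=acetate.as_function(), t_grid=t_grid)


@pytest.fixture(scope="session")
def noiseless_st_dataset():
    return generate_saturation_transfer_dataset(
        TruthRecord(), AcquisitionParams(noise_sd=0.0)
    )


# -- fast toy system for statistical studies --------------------------------


@pytest.fixture(scope="session")
def toy_cycle():
    return toy_condensation_cycle()


@pytest.fixture(scope="session")
def toy_system(toy_cycle):
    return assemble_mass_isotopomer_odes(toy_cycle, observed=["obs"])


@pytest.fixture(scope="session")
def toy_input():
    return lambda t: 0.8 * (1.0 - np.exp(-t / 30.0))


@pytest.fixture(scope="session")
def toy_t_grid():
    return np.linspace(0.0, 120.0, 7)


@pytest.fixture(scope="session")
def toy_observations(toy_system, toy_input, toy_t_grid):
    """Noiseless observed table at the toy truth (F_cycle=0.05, F_exch=0.03)."""
    tc = simulate_labeling(toy_system, input_fn=toy_input, t_grid=toy_t_grid)
    return observations_from_timecourse(tc, metabolite="obs", sd=0.01)


@pytest.fixture(scope="session")
def fast_t_grid():
    """Short sampling grid for the Monte Carlo calibration studies."""
    return np.linspace(0.0, 60.0, 5)


@pytest.fixture(scope="session")
def fast_toy_observations(toy_system, toy_input, fast_t_grid):
    tc = simulate_labeling(toy_system, input_fn=toy_input, t_grid=fast_t_grid)
    return observations_from_timecourse(tc, metabolite="obs", sd=0.01)
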