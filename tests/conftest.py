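import numpy as np
import pytest

from mrtpbpk import (DoseEvent, GlobalKinetics, MrtParameters, SolverConfig,
                     build_model, load_species_physiology, simulate)


@pytest.fixture(scope="session")
def mouse_physiology():
    return load_species_physiology("mouse")


@pytest.fixture(scope="session")
def kinetics():
    return GlobalKinetics.default()


@pytest.fixture(scope="session")
def mrt_params():
    return MrtParameters.default()


@pytest.fixture(scope="session")
def mouse_model(mouse_physiology, kinetics, mrt_params):
    return build_model(mouse_physiology, kinetics, mrt_params)


@pytest.fixture(scope="session")
def study_dose():
    return DoseEvent(dose_mg_per_kg=10.0, body_weight=0.028,
                     molecular_weight=1.5e5)


@pytest.fixture(scope="session")
def mouse_simulation(mouse_model, study_dose):
    """Reference 168-h simulation on a half-hour grid (exact propagator)."""
    grid = np.round(np.arange(0.0, 168.0 + 0.25, 0.5), 10)
    return simulate(mouse_model, study_dose, grid,
                    solver=SolverConfig(method="expm"))
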