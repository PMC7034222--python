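import numpy as np
import pytest

import nanoflux as nf


@pytest.fixture(scope="session")
def nanofluid():
    """Study nanofluid: printed density, water viscosity at 25 C."""
    return nf.Fluid.nanofluid()


@pytest.fixture(scope="session")
def channel():
    """The 4 mm x 47 mm hydrogel channel."""
    return nf.Channel.from_mm()


@pytest.fixture(scope="session")
def fc_low():
    """Study conditions at 5.1 mm/s (the 4.12 g dose)."""
    return nf.study_flow_conditions(0.0051, inlet_mass_g=4.12)


@pytest.fixture(scope="session")
def fc_high():
    """Study conditions at 5.4 mm/s (the 2.008 g dose)."""
    return nf.study_flow_conditions(0.0054, inlet_mass_g=2.008)


@pytest.fixture(scope="session")
def study_mesh(channel):
    """The optimum 129 x 97 x 37 mesh of the grid study."""
    return nf.build_mesh(129, 97, 37, channel=channel)


@pytest.fixture(scope="session")
def diffusivity_144(nanofluid):
    """Stokes-Einstein diffusivity of the 144 nm formulation."""
    return nf.stokes_einstein_diffusivity(144e-9, nanofluid)


@pytest.fixture(scope="session")
def poiseuille_field(fc_low, study_mesh):
    return nf.VelocityField.fully_developed(fc_low, study_mesh)


@pytest.fixture(scope="session")
def eulerian_study_result(fc_low, diffusivity_144, poiseuille_field, study_mesh):
    """Graetz solve at the study conditions, shared across tests."""
    return nf.solve_graetz(fc_low, diffusivity_144, poiseuille_field, study_mesh)
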