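import numpy as np
import pytest

import aureole as a


@pytest.fixture
def geometry():
    """Default cell geometry: d_cell 22 um, V_cell 1600 um^3, A_cell 770 um^2."""
    return a.CellGeometry()


@pytest.fixture
def silica():
    return a.ParticleSpec(d_um=1.0, rho_kg_m3=2000.0, label="SiO2Carbo1000")


@pytest.fixture
def ps1000():
    return a.ParticleSpec(d_um=1.0, rho_kg_m3=1050.0, label="PsCarbo1000")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sio2_front_low():
    """Low-coverage silica front simulation, run long enough to pass 2 R_c."""
    cfg = a.SimConfig(preset="SiO2Carbo1000", phi_S=0.22, seed=1, duration_s=108000.0)
    return a.simulate_front_uptake(cfg)
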