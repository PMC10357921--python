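import numpy as np
import pytest

import esrdecouple as esr


@pytest.fixture(scope="session")
def r1_l():
    """Simulated L-band spectrum of the 175-line methylated-anthracene cation."""
    return esr.simulate_system("R1", band="L")


@pytest.fixture(scope="session")
def r2_s():
    """Simulated S-band spectrum of the bridged-biaryl cation."""
    return esr.simulate_system("R2", band="S")


@pytest.fixture(scope="session")
def m2_x():
    """Simulated X-band frozen-powder spectrum of the Cu-N4 adduct."""
    return esr.simulate_system("M2", band="X")


@pytest.fixture(scope="session")
def r1_l_decoupled(r1_l):
    return esr.pseudo_decouple(r1_l, j_star=7)


@pytest.fixture(scope="session")
def m2_x_decoupled(m2_x):
    return esr.pseudo_decouple(m2_x, j_star=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
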