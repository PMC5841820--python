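import numpy as np
import pytest

from hepstu.metabolic import EnzymeParameterSet
from hepstu.stu import assemble_stu, steady_state_stu
from hepstu.zonation import ZonationProfile, endpoint_params


@pytest.fixture(scope="session")
def params():
    return EnzymeParameterSet.default()


@pytest.fixture(scope="session")
def profile():
    return ZonationProfile.default(n_cells=20)


@pytest.fixture(scope="session")
def pph_pch(profile):
    return endpoint_params(profile)


@pytest.fixture(scope="session")
def stu_system():
    return assemble_stu()


@pytest.fixture(scope="session")
def stu_sweep(stu_system):
    """Steady states of the default STU over portal glucose 3..15 mM,
    warm-started along the grid; shared by the transport/hormone/property
    tests."""
    results, y0 = {}, None
    for glc in range(3, 16):
        r = steady_state_stu(stu_system, float(glc), y0=y0)
        y0 = r.state
        results[glc] = r
    return results


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240817)
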