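import numpy as np
import pytest

import chemodrop as cd


@pytest.fixture
def rng():
    return np.random.default_rng(20160414)


@pytest.fixture(scope="session")
def solved_gradient():
    """Default-operating-point gradient field (chemoeffector on the right inlet)."""
    return cd.solve_steady_gradient(inlet_concentrations=(0.0, 0.0, 1.0))


@pytest.fixture(scope="session")
def zero_gradient():
    """Buffer-everywhere control field on the same grid."""
    return cd.solve_steady_gradient(inlet_concentrations=(0.0, 0.0, 0.0))
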