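import numpy as np
import pytest

from pdlvisco import SLSParameters, SchaperyParameters, StepLoad
from pdlvisco.reference import CREEP_PARAMETERS


@pytest.fixture(scope="session")
def unit_context():
    """The conventional normalization: Etf = Em = 1 MPa, sigma0 = 1."""
    return dict(Etf=1.0, Em=1.0, sigma0=1.0)


@pytest.fixture(params=sorted(CREEP_PARAMETERS))
def reference_sample(request):
    """(name, SchaperyParameters, SLSParameters) for each published column."""
    name = request.param
    p = CREEP_PARAMETERS[name]
    sch = SchaperyParameters(g0=p["g0"], g1=1.0, g2=p["g2"])
    sls = SLSParameters(1.0, 1.0, p["eta"])
    return name, sch, sls


@pytest.fixture
def hold_grid():
    """The study's hold-stage time grid: 0..200 s, 201 points."""
    return np.linspace(0.0, 200.0, 201)
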