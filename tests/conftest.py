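import numpy as np
import pytest

from keraopt.datasets import load_fixture
from keraopt.rsm import fit_quadratic


@pytest.fixture(scope="session")
def pbd():
    """Embedded 12-run screening design with responses."""
    design, responses, frame = load_fixture("pbd_table1")
    return design, responses, frame


@pytest.fixture(scope="session")
def rccd():
    """Embedded 40-run central composite design with responses."""
    design, responses, frame = load_fixture("rccd_table2")
    return design, responses, frame


@pytest.fixture(scope="session")
def quad_model(rccd):
    design, responses, _ = rccd
    return fit_quadratic(design, responses)


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)
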