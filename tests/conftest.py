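import numpy as np
import pytest

import methanesource as ms


@pytest.fixture(scope="session")
def frame():
    return ms.ReferenceFrame()


@pytest.fixture(scope="session")
def calibration():
    return ms.load_calibration("eldridge2019")


@pytest.fixture(scope="session")
def endmembers():
    return ms.load_endmembers()


@pytest.fixture(scope="session")
def templates():
    return ms.load_site_templates()


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def random_composition(rng, clumped_scale=5.0):
    """A random natural-looking methane composition."""
    return ms.IsotopeComposition(
        d13C=float(rng.uniform(-110.0, -20.0)),
        dD=float(rng.uniform(-450.0, -90.0)),
        D13CH3D=float(rng.uniform(-clumped_scale, clumped_scale)),
        D12CH2D2=float(rng.uniform(-4 * clumped_scale, 4 * clumped_scale)),
    )
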