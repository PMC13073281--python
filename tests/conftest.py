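import numpy as np
import pytest

from stainmap.geometry import ScanGeometry
from stainmap.synthetic import ModulatorSpec, build_calibration_phantom


@pytest.fixture(scope="session")
def geometry():
    return ScanGeometry()


@pytest.fixture(scope="session")
def modulator():
    return ModulatorSpec()


@pytest.fixture(scope="session")
def small_phantom():
    """48^3 calibration phantom shared by the fast pipeline tests."""
    return build_calibration_phantom(n=48)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
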