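import numpy as np
import pytest

from protoplan import phantoms
from protoplan.grid_core import DoseGrid


@pytest.fixture(scope="session")
def default_phantom():
    """The seeded default thorax phantom (masks + density)."""
    return phantoms.generate_phantom()


@pytest.fixture(scope="session")
def reference_plan(default_phantom):
    """Reference dose + spot plan for the default phantom (robust mimic of
    the idealized prescription); shared because it is the expensive input
    to several downstream checks."""
    structures, density = default_phantom
    dose, plan = phantoms.generate_reference_dose(structures, density)
    return dose, plan


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def water_box():
    """Uniform unit-density 20^3 block at 2.5 mm spacing."""
    return DoseGrid(np.ones((20, 20, 20)), (2.5, 2.5, 2.5))
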