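import numpy as np
import pytest

from morphocanvas import (
    Canvas,
    ElasticMaterial,
    build_flat_sheet,
    isotropic_stiffness,
)


@pytest.fixture
def sheet10():
    return build_flat_sheet(10, 10, 1.0, 0.1, 0.0)


@pytest.fixture
def sheet4():
    return build_flat_sheet(4, 4, 1.0, 0.1, 0.0)


@pytest.fixture
def single_wedge():
    """One triangle extruded to a single regular wedge element."""
    mid = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    n = np.array([0.0, 0.0, 1.0])
    t = 0.1
    return Canvas(mid - 0.5 * t * n, mid + 0.5 * t * n, np.array([[0, 1, 2]]))


@pytest.fixture
def material():
    return ElasticMaterial(1.0, 0.3)


@pytest.fixture
def stiffness(material):
    return isotropic_stiffness(material)
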