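import numpy as np
import pytest

from hipshape.simulate import make_deformation_fields, make_hip_template


@pytest.fixture(scope="session")
def template():
    return make_hip_template()


@pytest.fixture(scope="session")
def fields(template):
    return make_deformation_fields(template)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_shape(rng, P=8, spread=10.0):
    """A non-degenerate random 2D configuration."""
    return rng.normal(0.0, spread, size=(P, 2))


def apply_similarity(points, scale, rot, tx, ty):
    c, s = np.cos(rot), np.sin(rot)
    R = np.array([[c, -s], [s, c]])
    return scale * points @ R.T + np.array([tx, ty])
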