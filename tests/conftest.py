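import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform


@pytest.fixture
def unit_square():
    """The four corners of the unit square."""
    return np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


@pytest.fixture
def circle_points():
    """A clean 40-point circle with one unambiguous hole."""
    ang = np.linspace(0, 2 * np.pi, 40, endpoint=False)
    return np.column_stack([np.cos(ang), np.sin(ang)])


def dist(points):
    return squareform(pdist(points))


@pytest.fixture
def right_triangle_off(tmp_path):
    """ASCII OFF file holding a single unit right triangle."""
    p = tmp_path / "tri.off"
    p.write_text("OFF\n3 1 0\n0 0 0\n1 0 0\n0 1 0\n3 0 1 2\n")
    return p
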