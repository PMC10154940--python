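import numpy as np
import pytest

from ornametrics import Outline


@pytest.fixture
def unit_square():
    return Outline([(0, 0), (1, 0), (1, 1), (0, 1)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_convex_polygon(rng, n_vertices=12, radius=1.0, center=(0.0, 0.0)):
    """Convex polygon from sorted angles with jittered radii."""
    ang = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    r = radius * rng.uniform(0.6, 1.0, n_vertices)
    pts = np.column_stack([center[0] + r * np.cos(ang),
                           center[1] + r * np.sin(ang)])
    return Outline(pts)


def disc_mask(radius, pad=3):
    """Binary disc: pixels whose center lies within `radius` of the middle."""
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[0:n, 0:n]
    c = radius + pad
    return (xx - c) ** 2 + (yy - c) ** 2 <= radius**2
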