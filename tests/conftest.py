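import numpy as np
import pytest

from husaxs.debye import debye_intensity
from husaxs.models import BuildSpec, build_bdna
from husaxs.profiles import AtomisticModel, ScatteringProfile
from husaxs.synthetic import default_qgrid


def sphere_intensity(q, radius, scale=1.0):
    """Closed-form uniform-sphere form factor [3(sin x − x cos x)/x³]²."""
    x = np.asarray(q) * radius
    return scale * (3 * (np.sin(x) - x * np.cos(x)) / x ** 3) ** 2


def sphere_pr(r, radius):
    """Closed-form distance distribution of a uniform sphere (support 0..2R)."""
    x = np.clip(np.asarray(r) / (2 * radius), 0, 1)
    p = 12 * x ** 2 * (2 - 3 * x + x ** 3)
    p[np.asarray(r) > 2 * radius] = 0.0
    return p


def grid_sphere(radius=20.0, spacing=1.5):
    """Uniform cell-centred cubic-grid filling of a sphere."""
    g = np.arange(-radius + spacing / 2, radius, spacing)
    x, y, z = np.meshgrid(g, g, g, indexing="ij")
    pts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    pts = pts[np.sum(pts ** 2, axis=1) <= radius ** 2]
    return AtomisticModel(pts, np.ones(len(pts)))


@pytest.fixture(scope="session")
def qgrid():
    return default_qgrid()


@pytest.fixture(scope="session")
def duplex():
    return build_bdna(BuildSpec(n_bp=80))


@pytest.fixture(scope="session")
def duplex_profile(duplex, qgrid):
    return debye_intensity(duplex, qgrid)


@pytest.fixture(scope="session")
def sphere20_profile(qgrid):
    return ScatteringProfile(qgrid, sphere_intensity(qgrid, 20.0))
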