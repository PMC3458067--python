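import numpy as np
import pytest

from longiseg4d import LevelSetField, LevelSetTriple


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def circle_sdf(n, radius, center=None, spacing=1.0):
    """Exact signed distance to a circle (positive inside)."""
    if center is None:
        center = ((n - 1) / 2.0, (n - 1) / 2.0)
    yy, xx = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing, indexing="ij")
    r = np.sqrt((yy - center[0] * spacing) ** 2 + (xx - center[1] * spacing) ** 2)
    return radius - r


@pytest.fixture
def nested_triple():
    """Concentric nested triple with a 3 mm GM band on a 64^2 unit grid."""
    n = 64
    return LevelSetTriple(
        LevelSetField(circle_sdf(n, 12.0), 1.0),
        LevelSetField(circle_sdf(n, 15.0), 1.0),
        LevelSetField(circle_sdf(n, 19.0), 1.0),
    )
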