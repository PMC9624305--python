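import numpy as np
import pytest

from neuromech import SubstrateProperties, TractionField


@pytest.fixture
def substrate() -> SubstrateProperties:
    """The soft polyacrylamide gel used throughout: 470 Pa, incompressible."""
    return SubstrateProperties(young_modulus=470.0, poisson_ratio=0.5)


@pytest.fixture
def balanced_traction() -> TractionField:
    """Band-limited, balanced two-dipole traction field on a 64x64 um grid."""
    n, dx = 64, 1.0
    ys, xs = np.mgrid[0:n, 0:n] * dx

    def gauss(cx, cy, s):
        return np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * s**2))

    tx = 50 * gauss(22, 32, 3.0) - 50 * gauss(42, 32, 3.0)
    ty = 30 * gauss(32, 22, 3.0) - 30 * gauss(32, 42, 3.0)
    return TractionField(grid_spacing=dx, tx=tx, ty=ty)
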