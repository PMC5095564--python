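import numpy as np
import pytest

from ssmholo import (
    BasisGeometry,
    IncidentField,
    capture_intensity,
    forward_propagate,
    generate_tm,
)


@pytest.fixture
def small_geometry():
    """8x8-mode basis on the default sensor FOV, modest rendering grid."""
    return BasisGeometry(nx=8, ny=8, grid_nx=32, grid_ny=32)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_pipeline():
    """Noiseless end-to-end scene at N=16, gamma=8 (TM, truth, intensity)."""
    tm = generate_tm(16, 8.0, seed=42)
    gen = np.random.default_rng(43)
    x = IncidentField(
        (gen.standard_normal(16) + 1j * gen.standard_normal(16)) / np.sqrt(2)
    )
    intensity = capture_intensity(forward_propagate(tm, x))
    return tm, x, intensity


def random_coeffs(n, seed):
    gen = np.random.default_rng(seed)
    return (gen.standard_normal(n) + 1j * gen.standard_normal(n)) / np.sqrt(2)
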