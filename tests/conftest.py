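import numpy as np
import pytest

from mrcprecon import (
    EncodingOperator,
    make_duct_phantom,
    make_equidistant_mask,
    simulate_acquisition,
    simulate_coil_maps,
)


@pytest.fixture(scope="session")
def phantom64():
    return make_duct_phantom(64, 64, 3, seed=7)


@pytest.fixture(scope="session")
def maps8():
    return simulate_coil_maps(64, 64, 8, seed=3)


@pytest.fixture(scope="session")
def noiseless_full_acq(phantom64, maps8):
    """Noiseless, fully sampled 8-coil acquisition of the 64x64 phantom."""
    return simulate_acquisition(phantom64, maps8, None, 0.0, seed=0)


@pytest.fixture(scope="session")
def r2_acq(phantom64, maps8):
    """Noiseless R=2 acquisition with a 16-line ACS block."""
    mask2 = make_equidistant_mask(64, 2, 16)
    return simulate_acquisition(phantom64, maps8, mask2, 0.0, seed=0), mask2


@pytest.fixture()
def small_operator():
    """16x16, 4-coil, R=2 encoding operator for dense linear-algebra oracles."""
    maps = simulate_coil_maps(16, 16, 4, seed=2)
    mask = make_equidistant_mask(16, 2, 6)
    return EncodingOperator(maps.maps, mask)


def dense_matrix(op: EncodingOperator) -> np.ndarray:
    """Explicit matrix of E, column by column (brute-force oracle helper)."""
    ny, nx = op.shape
    n = ny * nx
    mat = np.zeros((op.n_coils * n, n), dtype=complex)
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        mat[:, j] = op.forward(e.reshape(ny, nx)).ravel()
    return mat
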