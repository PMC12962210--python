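"""Shared fixtures: small phantoms, coil arrays and noiseless acquisitions."""

import numpy as np
import pytest

from rsnr import (
    NoiseCovariance,
    evaluate_sensitivities,
    make_coil_array,
    make_digital_subject,
    make_shepp_logan_volume,
    simulate_acquisition,
)


@pytest.fixture(scope="session")
def small_phantom():
    """32^3 phantom at 8 mm voxels (256 mm FOV)."""
    return make_shepp_logan_volume((32, 32, 32), voxel_size_mm=8.0)


@pytest.fixture(scope="session")
def phantom_coil(small_phantom):
    return make_coil_array("surface_conformal", small_phantom, 8, 70.0)


@pytest.fixture(scope="session")
def phantom_sens(phantom_coil, small_phantom):
    return evaluate_sensitivities(phantom_coil, small_phantom)


@pytest.fixture(scope="session")
def zero_cov8():
    return NoiseCovariance(np.zeros((8, 8), dtype=complex))


@pytest.fixture(scope="session")
def noiseless_kspace(small_phantom, phantom_sens, zero_cov8):
    return simulate_acquisition(small_phantom, phantom_sens, zero_cov8, seed=0)


@pytest.fixture(scope="session")
def supine_subject():
    return make_digital_subject("supine", 1000.0, seed=3)


@pytest.fixture(scope="session")
def prone_subject():
    return make_digital_subject("prone", 1000.0, seed=3)
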