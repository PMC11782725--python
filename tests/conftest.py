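import numpy as np
import pytest

import dpgre


@pytest.fixture(scope="session")
def six_vial_adcs():
    return [0.4e-3, 0.6e-3, 0.8e-3, 1.1e-3, 1.5e-3, 2.0e-3]


@pytest.fixture(scope="session")
def vial_volume(six_vial_adcs):
    """Standard six-vial phantom on the reduced-FOV acquisition grid."""
    return dpgre.make_vial_phantom(6, six_vial_adcs, grid_shape=(64, 32, 8))


@pytest.fixture(scope="session")
def small_volume():
    """Tiny single-vial phantom for fast unit tests."""
    return dpgre.make_vial_phantom(1, [1.1e-3], grid_shape=(16, 16, 4))


@pytest.fixture(scope="session")
def small_cfg():
    return dpgre.SequenceConfig(
        lines_per_shot=16, n_partitions=4, nav_lines=6, averages=(1, 1)
    )


@pytest.fixture(scope="session")
def std_cfg():
    """Acquisition matched to the 64x32x8 phantom grid, one average per b."""
    return dpgre.SequenceConfig(lines_per_shot=32, n_partitions=8, averages=(1, 1))


@pytest.fixture(scope="session")
def coil_sens_4():
    return dpgre.make_coil_sens(4, (64, 32), seed=5)


@pytest.fixture(scope="session")
def clean_acq(vial_volume, std_cfg, coil_sens_4):
    """Zero-noise, zero-phase-error acquisition of the six-vial phantom."""
    return dpgre.simulate_acquisition(
        vial_volume, std_cfg, coil_sens=coil_sens_4, seed=1
    )


@pytest.fixture(scope="session")
def clean_recon(clean_acq):
    return dpgre.reconstruct(clean_acq, correct=True)
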