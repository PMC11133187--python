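import numpy as np
import pytest

from nvcoupling import SimulationConfig, simulate_subject
from nvcoupling.imaging import extract_reference, preprocess


@pytest.fixture
def noise_free_cfg():
    return SimulationConfig(
        n_regions=7, voxels_per_region=12, n_venous_voxels=8,
        region_lags=[0, 1, -1, 2, -2, 3, -3], noise_sd=0.0,
        shared_signal_weight=0.0, seed=7,
    )


@pytest.fixture
def noise_free_subject(noise_free_cfg):
    return simulate_subject(noise_free_cfg, 0)


# The seeded noisy configuration used by the lag-recovery acceptance check:
# unit-variance latent + unit-variance voxel noise (signal fraction ~0.5).
NOISY_CFG = dict(
    n_regions=7, voxels_per_region=50, n_venous_voxels=20,
    region_lags=[0, 1, -1, 2, -2, 3, -3], noise_sd=1.0,
    shared_signal_weight=0.0, seed=42,
)


@pytest.fixture
def noisy_subject():
    return simulate_subject(SimulationConfig(**NOISY_CFG), 0)


def preprocessed_ref(bold, venous, band=(0.01, 0.08)):
    pre = preprocess(bold, band)
    return pre, extract_reference(pre, venous)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
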