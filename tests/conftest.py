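import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

import looplight as ll


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_masks():
    """Tiny brain / signal-ROI / control-ROI trio for fast end-to-end tests."""
    return ll.default_masks((14, 14, 10), roi_voxels=44)


@pytest.fixture(scope="session")
def zero_noise():
    return ll.NoiseParams(sigma_system=0.0, drift_amplitude=0.0, smooth_fwhm_mm=0.0)


@pytest.fixture(scope="session")
def hrf():
    return ll.double_gamma_hrf()


@pytest.fixture(scope="session")
def noiseless_session(small_masks, zero_noise, hrf):
    """One noiseless participant at full signal (N = 12, 25 repetitions)."""
    brain, roi, control = small_masks
    runs, events = ll.simulate_session(
        12, 25, 1.0, brain, roi, zero_noise, hrf, participant=0, base_seed=7
    )
    return runs, events


def random_distance_matrix(rng, n):
    pts = rng.standard_normal((n, 3))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return d
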