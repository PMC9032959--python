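import numpy as np
import pytest

from handmap.config import StudyConfig
from handmap import cortical, peripheral


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study: enough voxels for stable maps, fast to simulate."""
    return StudyConfig(n_participants=2, n_voxels=150, seed=123)


@pytest.fixture(scope="session")
def quiet_config():
    """Low-noise variant for analyses that assert near-noiseless recovery."""
    return StudyConfig(n_participants=1, n_voxels=150, noise_sd=0.05, seed=321)


@pytest.fixture(scope="session")
def drives():
    return peripheral.baseline_drives(peripheral.build_spread())


@pytest.fixture(scope="session")
def blocked_drives(drives):
    return peripheral.blocked_drives(drives, "D2", 0.2)


@pytest.fixture(scope="session")
def true_model():
    """Ground-truth recurrent model used by the fitting tests."""
    rng = np.random.default_rng(5)
    W = np.eye(5) + 0.1 * rng.random((5, 5))
    return cortical.CorticalModel(
        alpha=np.ones(5), W=W, b=0.3, L=cortical.lateral_matrix()
    )


@pytest.fixture(scope="session")
def baseline_target(true_model, drives):
    """Noiseless baseline activity table (condition x cluster) of true_model."""
    import numpy as np
    from handmap.config import FINGERS

    return np.column_stack(
        [cortical.fixed_point(true_model, drives[f]) for f in FINGERS]
    ).T
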