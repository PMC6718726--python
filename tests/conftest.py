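import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import radiosurv as rs

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def phantom_study():
    """One default phantom study with decoded masks."""
    study = rs.generate_phantom_study(rs.PhantomConfig(seed=1))
    masks = rs.study_masks(study)
    return study, masks


@pytest.fixture(scope="session")
def normalized_study(phantom_study):
    study, masks = phantom_study
    return rs.normalize_study(study, masks), masks


@pytest.fixture(scope="session")
def random_patches():
    """100 random 8x8 grey-level patches with non-trivial masks."""
    rng = np.random.default_rng(20240917)
    patches = []
    for _ in range(100):
        img = rng.integers(0, 256, (8, 8)).astype(np.float64)
        mask = rng.random((8, 8)) < 0.8
        mask[3:5, 3:5] = True  # guarantee adjacent in-mask pixels
        patches.append((img, mask))
    return patches
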