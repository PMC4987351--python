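import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import hubdisrupt as hd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small disrupted cohort reused by several slow-ish integration tests."""
    spec = hd.CohortSpec(
        n_controls=6, n_patients=6, n_patients_left_lesion=3,
        n_nodes=20, n_timepoints=256, seed=7,
    )
    return hd.simulate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_profiles(tiny_cohort):
    from hubdisrupt import analysis

    return analysis.cohort_profiles(tiny_cohort, [0.2, 0.3])
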