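import numpy as np
import pytest

from eegtrp import CohortSpec, default_montage, synth_subject_session


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def short_session():
    """One simulated subject with compact segments, reused across tests."""
    spec = CohortSpec(baseline_s=20.0,
                      seg1_s={"isometric": 8.0, "orthographic": 8.0},
                      seg2_s={"isometric": 20.0, "orthographic": 20.0})
    return synth_subject_session(spec, "s01", seed=1234)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
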