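import numpy as np
import pytest

from handsight.analysis import AnalysisParams
from handsight.cohort import CohortConfig


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """A compact cohort used by the slower integration tests."""
    return CohortConfig(n_onehanders=8, n_controls=6, grid_dims=(16, 16, 10),
                        n_vols_rest=120, controls_missing_questionnaire=1,
                        controls_without_localizer=1, seed=11)


@pytest.fixture(scope="session")
def fast_params():
    return AnalysisParams(n_permutations=200)
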