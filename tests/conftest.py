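import numpy as np
import pytest

from symbrain import (
    StudyConfig,
    SyntheticConnectomeSpec,
    generate_synthetic_connectome,
    run_study,
)

#: structural matrix used by the study-level fixtures; one fixed realization
#: plays the role of the single empirical matrix of the study design
CONNECTOME_SEED = 1
STUDY_BASE_SEED = 7


@pytest.fixture(scope="session")
def connectome78():
    return generate_synthetic_connectome(
        SyntheticConnectomeSpec(n_regions=78, seed=CONNECTOME_SEED)
    )


@pytest.fixture(scope="session")
def small_connectome():
    return generate_synthetic_connectome(
        SyntheticConnectomeSpec(n_regions=20, seed=3)
    )


@pytest.fixture(scope="session")
def study(connectome78):
    """The S = 1 column of the study: five Vd2 models x 10 runs x 3 conditions.

    Computed once per test session; several study-level tests read from it.
    """
    config = StudyConfig(s_grid=(1.0,), base_seed=STUDY_BASE_SEED)
    return run_study(config, connectome78)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
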