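import warnings

import numpy as np
import pytest

import mlmgm

warnings.filterwarnings("ignore", message="Random effects covariance is singular")
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def cohort_grid():
    return mlmgm.make_cohort_grid(mlmgm.COHORT_DEFAULT, seed=11)


@pytest.fixture(scope="session")
def accelerated_grid():
    return mlmgm.make_accelerated_grid(mlmgm.ACCELERATED_DEFAULT, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
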