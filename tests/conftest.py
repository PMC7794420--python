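import numpy as np
import pytest

from prm3d.phantom import PhantomParams, Subject, iter_cohort


@pytest.fixture(scope="session")
def params() -> PhantomParams:
    return PhantomParams()


@pytest.fixture(scope="session")
def two_subjects(params) -> list[Subject]:
    """One COPD and one non-COPD phantom, shared across tests."""
    return list(iter_cohort(1, 1, params, seed=11))


@pytest.fixture(scope="session")
def copd_subject(two_subjects) -> Subject:
    return two_subjects[0]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
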