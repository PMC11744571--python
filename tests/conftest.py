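import numpy as np
import pandas as pd
import pytest

from exercog.simulate import generate_covariates, null_profile, paper_effects


@pytest.fixture(scope="session")
def profile():
    return paper_effects()


@pytest.fixture(scope="session")
def null_prof():
    return null_profile()


@pytest.fixture(scope="session")
def covariates71(profile):
    return generate_covariates(profile, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
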