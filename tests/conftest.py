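import numpy as np
import pandas as pd
import pytest

import kinflux as kf


@pytest.fixture(scope="session")
def toy():
    """Toy central-carbon model with its Kcat table and expression."""
    model, kcats, expression = kf.make_toy_model(kf.ToySpec(seed=1))
    return model, kcats, expression


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def chain_model():
    return kf.make_chain_model()


@pytest.fixture(scope="session")
def cohort():
    """Synthetic cohort with a planted up-shifted subsystem (SS01)."""
    return kf.make_synthetic_cohort(kf.CohortSpec(seed=1, effect=1.5))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
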