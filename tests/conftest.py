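import numpy as np
import pytest

from osteomir.cohort import MODEL_FEATURES, fit_minmax
from osteomir.dann import train_dann
from osteomir.simulate import (
    GeneratorConfig,
    external_cohort_config,
    generate_cohort,
)


@pytest.fixture(scope="session")
def harbin_like():
    """Synthetic stand-in for the main study cohort (n=230)."""
    return generate_cohort(GeneratorConfig(), seed=1)


@pytest.fixture(scope="session")
def external_like():
    """Synthetic stand-in for the external-validation cohort (n=30)."""
    return generate_cohort(external_cohort_config(), seed=11)


@pytest.fixture(scope="session")
def trained_dann(harbin_like):
    """One full DANN training run, shared across tests that only read it."""
    model, diag = train_dann(harbin_like, MODEL_FEATURES, seed=1)
    return model, diag


@pytest.fixture(scope="session")
def normalization(harbin_like):
    return fit_minmax(harbin_like, (*MODEL_FEATURES, "bmd"))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
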