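import numpy as np
import pytest

from mosdet import model as mdl
from mosdet import preprocess as pp
from mosdet import simulate as sim


@pytest.fixture(scope="session")
def easy_cohort():
    """Six-subject fully-responding cohort with mild noise."""
    recordings, manifest = sim.gen_cohort(6, sim.easy_ranges(), rng_seed=7)
    return recordings, manifest


@pytest.fixture(scope="session")
def easy_windows(easy_cohort):
    recordings, _ = easy_cohort
    return pp.windows_from_cohort(recordings)


@pytest.fixture(scope="session")
def small_hyperparams():
    return mdl.Hyperparams(hidden_size=16, max_epochs=15, patience=4,
                           batch_size=128)


@pytest.fixture(scope="session")
def trained_classifier(easy_windows, small_hyperparams):
    return mdl.train(easy_windows, small_hyperparams, rng_seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
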