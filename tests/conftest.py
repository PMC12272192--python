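import numpy as np
import pytest

from apnoea_eeg.simulate import SimConfig, make_labelled_candidates


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cfg():
    """A short cohort: enough pauses for recovery checks, cheap to simulate."""
    return SimConfig(n_infants=6, duration_s=900.0, seed=7)


@pytest.fixture(scope="session")
def default_candidates():
    """Labelled candidate set at the default generator separation."""
    cfg = SimConfig(n_infants=10, seed=42)
    return make_labelled_candidates(cfg, n_true=100, n_false=100)
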