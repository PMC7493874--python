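import numpy as np
import pytest

from fpscreen import generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Small planted-signal dataset shared by model-level tests."""
    return generate_dataset(n_active=80, n_inactive=640, seed=11)


@pytest.fixture(scope="session")
def easy_dataset():
    """Perfect-signal dataset (q=1, no noise): separable by construction."""
    return generate_dataset(
        n_active=100, n_inactive=400, q_signal=1.0, noise_rate=0.0, seed=7
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
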