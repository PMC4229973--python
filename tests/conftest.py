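import numpy as np
import pytest

from hoppi.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def small_synth():
    """A small planted-signal dataset shared across fast tests."""
    return generate(
        SyntheticConfig(n_proteins=60, n_positive=60, neg_ratio=5, seed=7)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
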