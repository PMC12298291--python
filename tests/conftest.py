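import numpy as np
import pytest

from iihgnn.data import SynthConfig, generate_synthetic_dataset


@pytest.fixture(scope="session")
def smoke_dataset():
    """Small deterministic synthetic dataset shared across tests."""
    return generate_synthetic_dataset(SynthConfig.smoke(n_images=24, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
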