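import numpy as np
import pytest

from sonoseg import PhantomConfig, build_model, generate_dataset


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig(seed=0)


@pytest.fixture(scope="session")
def small_dataset(phantom_config):
    """Eight easy phantoms shared across tests (read-only)."""
    samples, manifest = generate_dataset(8, phantom_config, seed=11)
    return samples, manifest


@pytest.fixture(scope="session")
def tiny_model():
    """Tiny-backbone assembly with the full-size (256-dim) decoder."""
    return build_model("tiny", seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
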