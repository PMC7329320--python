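import numpy as np
import pytest

from stoichres import EffectConfig, generate_experiment
from stoichres.panel import default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_bundle():
    """A compact default-config experiment shared across read-only tests."""
    return generate_experiment(EffectConfig(), n_sites=20, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
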