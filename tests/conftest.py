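import numpy as np
import pytest

from microarousal import SyntheticConfig, generate_recording


@pytest.fixture(scope="session")
def small_bundle():
    """One 30-min synthetic recording shared across read-only tests."""
    return generate_recording(SyntheticConfig(seed=42, duration_s=1800.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
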