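import numpy as np
import pytest

from dermoclass import synth


@pytest.fixture(scope="session")
def small_dataset():
    """Ten images per class at default study conditions (session-cached)."""
    config = synth.SynthConfig(n_per_class=10, seed=1234)
    return synth.generate_dataset(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
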