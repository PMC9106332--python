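import numpy as np
import pytest

from modinvar import task


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def chord_bank():
    """Default chord sources, long enough for small training batches."""
    return task.generate_sources(T=4000)


@pytest.fixture(scope="session")
def long_chord_bank():
    return task.generate_sources(T=16000)
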