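import numpy as np
import pytest

from synsplice import sequences


@pytest.fixture(scope="session")
def variants():
    return sequences.splice_isoforms()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
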