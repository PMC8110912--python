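import numpy as np
import pytest

from helpers import rep_from_reads


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_rep():
    """5 clones, reads 10/5/3/1/1, distinct nt and aa keys."""
    return rep_from_reads([10, 5, 3, 1, 1], sample_id="small")
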