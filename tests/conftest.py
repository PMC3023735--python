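import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

BASES = np.array(list("ACGT"))


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def rand_seq(rng, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])
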