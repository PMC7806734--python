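import numpy as np
import pytest
from hypothesis import settings

from vis4m.maze import COLOR_ARMS

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def random_collapsed_sequence(rng, n, arms=COLOR_ARMS):
    """Random arm sequence with no consecutive repeats (not the null model:
    arbitrary non-uniform draws are fine here)."""
    seq = [arms[rng.integers(len(arms))]]
    while len(seq) < n:
        nxt = arms[rng.integers(len(arms))]
        if nxt != seq[-1]:
            seq.append(nxt)
    return seq
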