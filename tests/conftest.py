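import numpy as np
import pytest

from evodiv.phenotype_gxe import ODMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_od_matrix(rng, g=5, s=8, scale=1.0):
    """A random non-negative clone x substrate matrix."""
    values = rng.uniform(0.05, scale, size=(g, s))
    return ODMatrix(
        values,
        [f"c{i}" for i in range(g)],
        [f"s{j}" for j in range(s)],
        population_id="test",
    )
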