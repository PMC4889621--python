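import numpy as np
import pytest

from casafusion import GridSpec


@pytest.fixture
def spec5() -> GridSpec:
    return GridSpec(-111.0, 45.0, 0.004, 5, 5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160602)


def idw_brute(sample_xy, sample_z, query_xy, power):
    """All-pairs reference IDW: explicit weight sums, coincident points by mean."""
    out = np.empty(len(query_xy))
    for i, q in enumerate(query_xy):
        d = np.sqrt(((sample_xy - q) ** 2).sum(axis=1))
        hit = d == 0.0
        if hit.any():
            out[i] = sample_z[hit].mean()
        else:
            w = d ** (-power)
            out[i] = (w * sample_z).sum() / w.sum()
    return out
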