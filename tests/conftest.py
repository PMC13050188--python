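import numpy as np
import pytest

from famvar.params import LocusParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mixed_locus():
    """A locus with all five effect classes active."""
    return LocusParams(q2=0.3, beta_c=1.0, beta_m=0.5, beta_f=-0.5, beta_i=0.2, beta_s=0.3)


def random_locus(rng, with_sibling=True):
    """Random locus draw used by oracle-equivalence style tests."""
    return LocusParams(
        q2=rng.uniform(0.05, 0.95),
        beta_c=rng.uniform(-1, 1),
        beta_m=rng.uniform(-1, 1),
        beta_f=rng.uniform(-1, 1),
        beta_i=rng.uniform(-1, 1),
        beta_s=rng.uniform(-1, 1) if with_sibling else 0.0,
    )
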