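import numpy as np
import pytest

from cinephase import SyntheticCineSpec, generate

# reduced grid for fast tests; the acceptance suite uses the full default grid
SMALL_SHAPE = (10, 40, 44)
SMALL_EDV = 300.0


def small_spec(**kw) -> SyntheticCineSpec:
    base = dict(shape=SMALL_SHAPE, edv_ul=SMALL_EDV, n_phases=11, seed=0)
    base.update(kw)
    return SyntheticCineSpec(**base)


@pytest.fixture(scope="session")
def small_result():
    """One small synthetic cine series shared across read-only tests."""
    return generate(small_spec())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
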