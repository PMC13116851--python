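import numpy as np
import pytest

from viewgate.synthdata import SyntheticSpec, generate


@pytest.fixture(scope="session")
def default_spec():
    """The reference synthetic study conditions (8 views, 3 informative)."""
    return SyntheticSpec(seed=0)


@pytest.fixture(scope="session")
def default_dataset(default_spec):
    return generate(default_spec)


@pytest.fixture(scope="session")
def tiny_spec():
    """A minutes-scale-down spec for fast training smoke tests."""
    return SyntheticSpec(n_classes=4, n_views=5, informative_views=(1, 3),
                         n_train=80, n_val=24, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    return generate(tiny_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
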