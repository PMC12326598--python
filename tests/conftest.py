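import numpy as np
import pytest

from toxembed import synthetic
from toxembed.nn import autograd as ag


@pytest.fixture(scope="session")
def small_corpus():
    """A 300-molecule synthetic corpus shared across test modules."""
    spec = synthetic.SyntheticSpec(n_molecules=300, seed=7)
    return synthetic.generate_corpus(spec)


@pytest.fixture(scope="session")
def small_study(small_corpus):
    return synthetic.generate_invivo_study(small_corpus, small_corpus.spec)


@pytest.fixture
def float64_graph():
    """Run the autograd engine in float64 for finite-difference checks."""
    previous = ag.DTYPE
    ag.set_default_dtype(np.float64)
    yield
    ag.set_default_dtype(previous)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
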