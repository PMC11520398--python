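import warnings

import pytest

from moldialog import gen_corpus

# empty-fingerprint warnings from single-atom molecules are expected in bulk runs
warnings.filterwarnings("ignore", message="tanimoto of two empty fingerprints")


@pytest.fixture(scope="session")
def corpus():
    """A mid-sized synthetic corpus shared across test modules."""
    return gen_corpus(40, seed=11)


@pytest.fixture(scope="session")
def small_corpus():
    return gen_corpus(12, seed=7)
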