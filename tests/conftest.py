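import numpy as np
import pytest

from psfunc import build_trimer_ref, extract_windows
from psfunc.synthetic import load_example_query


@pytest.fixture(scope="session")
def example_seq() -> str:
    """The 270 bp worked-example query shipped with the package."""
    return load_example_query()


@pytest.fixture(scope="session")
def frame2_windows(example_seq):
    return extract_windows(example_seq, frame=2)


@pytest.fixture(scope="session")
def full_ref(frame2_windows):
    """Reference covering every amino-acid trimer of the example's frame 2."""
    return build_trimer_ref([w.aa_trimer for w in frame2_windows], "all_synonymous")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
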