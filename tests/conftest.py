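import warnings

import pytest

from helixcharge import Alignment, SyntheticConfig, generate, parse_newick


@pytest.fixture
def small_aln() -> Alignment:
    return Alignment(ids=["a", "b", "c"], rows=["MK-", "M-R", "MKR"])


@pytest.fixture
def worked_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def default_dataset():
    """The default three-family dataset (trait-coupled), seed 1."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """A fast 10-per-family dataset for pipeline-level tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate(SyntheticConfig(seed=2, n_per_family=10))
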