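import pytest

from epilocus import build_locus


@pytest.fixture(scope="session")
def default_locus_truth():
    return build_locus(seed=7)


@pytest.fixture(scope="session")
def locus(default_locus_truth):
    return default_locus_truth[0]


@pytest.fixture(scope="session")
def truth(default_locus_truth):
    return default_locus_truth[1]
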