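import pytest

from aminescaffolds import enumerate_all, generate_all


@pytest.fixture(scope="session")
def full_skeletons():
    """The complete ring-system set for sizes {5,6,7}."""
    return generate_all({5, 6, 7})


@pytest.fixture(scope="session")
def full_scaffolds(full_skeletons):
    """The complete enumerated scaffold set (computed once per session)."""
    return enumerate_all(full_skeletons)
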