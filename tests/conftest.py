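import pytest

from tandemscan import ScoringScheme, make_fixture_genome


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def short_scheme():
    return ScoringScheme.short_preset()


@pytest.fixture(scope="session")
def micro_scheme():
    """Units 1-6 only: the range used for oracle comparisons."""
    return ScoringScheme(unit_min=1, unit_max=6)


@pytest.fixture(scope="session")
def fixture_bundle():
    """One deterministic genome fixture shared across the session."""
    return make_fixture_genome(seed=11)
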