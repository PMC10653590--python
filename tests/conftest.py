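import pytest

from ormine import build_family_profiles, simulate


@pytest.fixture(scope="session")
def seed_families():
    return simulate.make_seed_families()


@pytest.fixture(scope="session")
def profiles(seed_families):
    return build_family_profiles(seed_families, require_complete=True)


@pytest.fixture(scope="session")
def panel():
    return simulate.make_reference_panel()
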