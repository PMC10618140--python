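import pytest

from nevi import build_default_registry, build_sensitivity_registry, toy_fixture


@pytest.fixture(scope="session")
def default_registry():
    return build_default_registry()


@pytest.fixture(scope="session")
def sensitivity_registry():
    return build_sensitivity_registry()


@pytest.fixture(scope="session")
def toy():
    """(feature table, registry, expected scores) for the 5-tract toy fixture."""
    return toy_fixture()
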