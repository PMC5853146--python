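import pytest

from glycoce.reference import build_reference_table
from glycoce.synth import CompositionModel, MigrationModel, compose_profile


@pytest.fixture(scope="session")
def ref():
    return build_reference_table()


@pytest.fixture(scope="session")
def composition():
    return CompositionModel()


@pytest.fixture(scope="session")
def migration():
    return MigrationModel()


@pytest.fixture(scope="session")
def ra_like_areas():
    """A hypogalactosylated composition typical of active RA."""
    return compose_profile(1.25, 41.5)
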