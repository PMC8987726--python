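import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_data():
    """The packaged 64-spectrum fixture and the 25-compound registry."""
    from camptomine.fixture import paper_fixture

    return paper_fixture()


@pytest.fixture(scope="session")
def alkaloids(fixture_data):
    spectra, _ = fixture_data
    return [s for s in spectra if s.metadata["series"] == "alkaloid"]


@pytest.fixture(scope="session")
def registry(fixture_data):
    return fixture_data[1]


@pytest.fixture(scope="session")
def fixture_annotation(alkaloids, registry):
    """Nominal-mode annotation table for the 40 fixture alkaloids."""
    from camptomine.fragrules import annotate

    return annotate(alkaloids, registry, mode="nominal")
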