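import warnings

import pytest
from hypothesis import HealthCheck, settings

from rbdrive.io import FixtureProvenanceWarning, load_centromere_fixture, load_offspring_fixture
from rbdrive.segregation import SegregationModel, observed_distribution

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def offspring_records():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FixtureProvenanceWarning)
        return load_offspring_fixture()


@pytest.fixture(scope="session")
def female_dist(offspring_records):
    return observed_distribution(offspring_records, "female")


@pytest.fixture(scope="session")
def male_dist(offspring_records):
    return observed_distribution(offspring_records, "male")


@pytest.fixture(scope="session")
def mendelian_model():
    return SegregationModel.mendelian(8)


@pytest.fixture(scope="session")
def centromere_fixture():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FixtureProvenanceWarning)
        return load_centromere_fixture()
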