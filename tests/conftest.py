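import pytest
from hypothesis import HealthCheck, settings

from dogpop import apply_quota, paper_survey_fixture
from dogpop.bayes_population import McmcSettings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def raw_fixture():
    return paper_survey_fixture()


@pytest.fixture(scope="session")
def fixture_ds(raw_fixture):
    """The in-study survey fixture with the 30-valid quota applied."""
    return apply_quota(raw_fixture, 30)


@pytest.fixture
def quick_mcmc():
    """Reduced-length sampler settings for fast unit tests."""
    def make(seed=0, **kw):
        kw.setdefault("n_iterations", 20_000)
        kw.setdefault("burn_in", 4_000)
        kw.setdefault("thin", 10)
        return McmcSettings(seed=seed, **kw)
    return make
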