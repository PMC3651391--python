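import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_model():
    from codp import default_model

    return default_model()


@pytest.fixture(scope="session")
def domain_map():
    from codp import msh6_domain_map

    return msh6_domain_map()


@pytest.fixture(scope="session")
def classified_variants():
    from codp import load_classified_variants

    return load_classified_variants()


@pytest.fixture(scope="session")
def uv_scores():
    from codp import load_uv_scores

    return load_uv_scores()
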