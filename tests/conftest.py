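import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_promoter():
    """A small promoter with one planted non-template site 91 bases upstream."""
    from crisprakit.fixtures import FixtureSpec, make_promoter_with_sites

    return make_promoter_with_sites(FixtureSpec(rng_seed=11))
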