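import pytest

from colonynet import SyntheticConfig, simulate_study


@pytest.fixture(scope="session")
def tiny_config():
    """A desk-scale two-year study used across the suite."""
    return SyntheticConfig(
        n_years=2, colonies_per_year=2, birds_per_colony=6,
        days_pre=3, days_post_by_year=(3, 2), frames_per_day=150,
        humidity_missing_days=1, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return simulate_study(tiny_config)
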