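import pytest

from airburden import ScenarioConfig, make_scenario


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale scenario: 20x20 grid, three years, two stages."""
    return ScenarioConfig(n_rows=20, n_cols=20, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return make_scenario(small_config, n_draws=8)
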