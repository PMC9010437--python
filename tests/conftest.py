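import pytest

import migflows as mf


@pytest.fixture(scope="session")
def small_world():
    """A 6-country, 2-period synthetic world with derived net migration."""
    cfg = mf.WorldConfig(n_countries=6, n_periods=2, seed=7)
    stocks, demo, true_flows = mf.generate_world(cfg)
    return stocks, mf.derive_net_migration(demo), true_flows


@pytest.fixture(scope="session")
def harmonized_world(small_world):
    stocks, demo, _ = small_world
    return mf.harmonize(stocks, demo)


@pytest.fixture(scope="session")
def pr_fixture():
    stocks, demo = mf.puerto_rico_fixture()
    return stocks, mf.derive_net_migration(demo)
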