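import pandas as pd
import pytest

from carbbudget.pipeline import compute_budgets
from carbbudget.reference_data import load_rate_tables
from carbbudget.synthetic import ReefscapeConfig, simulate_reefscape


@pytest.fixture(scope="session")
def library():
    return load_rate_tables()


@pytest.fixture(scope="session")
def default_reefscape():
    """The packaged default synthetic scenario at its default seed."""
    return simulate_reefscape(ReefscapeConfig(seed=0))


@pytest.fixture(scope="session")
def default_budgets(default_reefscape, library):
    d = default_reefscape
    return compute_budgets(d.benthic, d.fish, d.urchins, d.sponges,
                           d.substrate, d.sites, library)


@pytest.fixture(scope="session")
def noise_free_reefscape():
    return simulate_reefscape(ReefscapeConfig(seed=3).noise_free())


@pytest.fixture(scope="session")
def noise_free_budgets(noise_free_reefscape, library):
    d = noise_free_reefscape
    return compute_budgets(d.benthic, d.fish, d.urchins, d.sponges,
                           d.substrate, d.sites, library)


@pytest.fixture
def toy_cover():
    """One site-year, one transect: 3 calcifiers plus substrate."""
    return pd.DataFrame({
        "site_id": ["X"] * 4, "year": [2000] * 4, "transect_id": ["T1"] * 4,
        "taxon": ["A", "B", "CCA", "bare substrate"],
        "cover_pct": [10.0, 20.0, 30.0, 40.0],
    })
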