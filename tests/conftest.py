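import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import vaquitrend as vt

settings.register_profile("ci", max_examples=25, derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_truth():
    """Compact generator setup: 10 sites, 4 years, moderate decline."""
    return vt.SyntheticTruth(
        n_sites=10,
        extent_km=(20.0, 16.0),
        years=(2011, 2012, 2013, 2014),
        initial_mean_clicks=6.0,
        lambda_path=(0.7, 0.9, 0.6),
        sigma2_eps=0.2,
        sigma2_z=0.3,
        rho=8.0,
        missing_year_prob=(0.2, 0.1, 0.0, 0.0),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    dataset, realization = vt.simulate_dataset(small_truth)
    return dataset, realization


@pytest.fixture(scope="session")
def short_config():
    return vt.MCMCConfig(n_burn=400, n_keep=800, thin=2, seed=7)


@pytest.fixture(scope="session")
def fitted(small_dataset, short_config):
    """One short fit shared by the diagnostics / trend / projection tests."""
    dataset, realization = small_dataset
    draws = vt.fit(dataset, config=short_config, check_convergence=False)
    return dataset, realization, draws


@pytest.fixture
def toy_grid():
    return vt.SiteGrid(site_ids=(1, 2), coords_km=np.array([[0.0, 0.0], [5.0, 0.0]]))


@pytest.fixture
def toy_dataset(toy_grid):
    summaries = pd.DataFrame(
        {
            "year": [2011, 2011, 2012, 2012],
            "site_id": [1, 2, 1, 2],
            "W": [4.0, 2.0, 1.5, 0.5],
            "n": [50, 40, 60, 30],
        }
    )
    return vt.MonitoringDataset(grid=toy_grid, summaries=summaries)
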