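import numpy as np
import pandas as pd
import pytest

from orgfield.config import SimConfig, TrueParams
from orgfield import synthetic

KEY = ["permit", "site", "year"]


def zero_messiness() -> dict:
    return {k: 0.0 for k in SimConfig().registry_messiness}


@pytest.fixture(scope="session")
def clean_bundle():
    """Small synthetic county with a perfectly clean registry."""
    cfg = SimConfig(n_farms=60, seed=2, registry_messiness=zero_messiness())
    return cfg, synthetic.simulate_all(cfg, TrueParams())


@pytest.fixture(scope="session")
def messy_bundle():
    """Synthetic county with default (repairable) registry corruption."""
    cfg = SimConfig(n_farms=80, seed=3)
    return cfg, synthetic.simulate_all(cfg, TrueParams())


@pytest.fixture(scope="session")
def tau0_frame():
    """Covariate-level two-part draw with no group heterogeneity."""
    params = TrueParams(tau2_h1=0.0, tau2_h2=0.0)
    return params, synthetic.simulate_hurdle_frame(params, n_farms=300, seed=3)


@pytest.fixture(scope="session")
def re_frame():
    """Covariate-level draw with random intercepts in both hurdles."""
    params = TrueParams()
    return params, synthetic.simulate_hurdle_frame(
        params, n_farms=500, fields_per_farm_mean=8.0, seed=4)


def design(df: pd.DataFrame) -> np.ndarray:
    return np.column_stack([
        np.ones(len(df)),
        df.organic.to_numpy(dtype=float),
        np.log(df.area_adj_ha.to_numpy(dtype=float)),
        np.log(df.farm_size_ha.to_numpy(dtype=float)),
        df.storie.to_numpy(dtype=float),
    ])
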