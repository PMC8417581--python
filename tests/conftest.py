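import numpy as np
import pandas as pd
import pytest

from connectopath import make_default_covariance_spec, make_mesh, simulate_cohort


@pytest.fixture(scope="session")
def strip_mesh():
    """50-vertex two-row strip with a known gradient axis."""
    return make_mesh(25, 2)


@pytest.fixture(scope="session")
def cov_spec():
    return make_default_covariance_spec()


@pytest.fixture(scope="session")
def small_cohort():
    """8 + 8 subjects with ROI blocks; shared across read-only tests."""
    return simulate_cohort(8, 8, T=150, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def glm_covariates():
    """Non-degenerate covariate table for 40 subjects (20 case / 20 control)."""
    r = np.random.default_rng(99)
    n = 40
    return pd.DataFrame(
        {
            "group": ["case"] * 20 + ["control"] * 20,
            "age": r.uniform(8, 40, n),
            "fd": np.abs(r.normal(0, 0.1, n)),
            "site": ["siteA", "siteB"] * 20,
        }
    )
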