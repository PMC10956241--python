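import numpy as np
import pytest

import stareal as st


@pytest.fixture(scope="session")
def grid3():
    """3x3 lattice map with queen weights (9 zones)."""
    zm = st.generate_zone_map(3, seed=0)
    Wb = st.contiguity_from_map(zm, "queen")
    return zm, Wb, st.row_standardize(Wb)


@pytest.fixture(scope="session")
def study_map():
    """Study-scale 65-zone map with row-standardized queen weights."""
    zm = st.default_zone_map(seed=0)
    W = st.row_standardize(st.contiguity_from_map(zm, "queen"))
    return zm, W


@pytest.fixture(scope="session")
def small_gns_panel(grid3):
    """A 9-zone, 6-wave panel simulated from a mild GNS process."""
    zm, _, W = grid3
    params = st.GNSParams(
        rho=0.2, phi=0.3, gamma=-0.1, lam=0.2,
        beta=np.array([0.5, -0.4]), theta=np.array([0.3, 0.1]), sigma2=0.01,
    )
    X, names = st.generate_covariates(W, T=6, k=2, seed=11)
    panel = st.simulate_gns_panel(zm, W, params, X, T=6, seed=12, covariate_names=names)
    return panel, W, params
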