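import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from discboost import (DiscreteSurvivalData, ModelState, TimeGrid,
                       build_reduced_basis)


@pytest.fixture(scope="session")
def toy_data():
    """Small deterministic dataset: n=8, S=6, P=3."""
    rng = np.random.default_rng(42)
    Z = rng.standard_normal((8, 3))
    T = np.array([6, 2, 3, 1, 6, 5, 4, 6])
    delta = np.array([1, 0, 1, 1, 0, 1, 1, 0])
    return DiscreteSurvivalData(Z, T, delta, TimeGrid(np.arange(1.0, 7.0)))


@pytest.fixture(scope="session")
def toy_basis(toy_data):
    return build_reduced_basis(toy_data.grid, K=5)


@pytest.fixture()
def random_state(toy_data, toy_basis):
    rng = np.random.default_rng(7)
    st = ModelState.zeros(toy_data.grid.S, toy_data.P, toy_basis.K1)
    st.gamma[:] = rng.normal(scale=0.5, size=toy_data.grid.S)
    st.phi[:] = rng.normal(scale=0.3, size=toy_data.P)
    st.theta[:] = rng.normal(scale=0.2, size=st.theta.shape)
    st.alpha = {(0, 1): 0.25, (1, 2): -0.4}
    return st


@pytest.fixture(scope="session")
def sim_small():
    """Moderate simulated dataset with one dominant signal (for selection tests)."""
    from discboost import make_dataset, scenario_preset

    spec = scenario_preset("highdim", n=300, P=10, seed=5)
    return make_dataset(spec)
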