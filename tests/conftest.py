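import numpy as np
import pytest

import comreach as cr


@pytest.fixture(scope="session")
def prior():
    return cr.GaussianMixture1D.ratio_prior()


@pytest.fixture(scope="session")
def geometry():
    return cr.TaskGeometry()


@pytest.fixture(scope="session")
def group_params():
    """Fitted group-level observer parameters used as simulation truth."""
    return cr.GROUP_FIT_PARAMS


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort(group_params):
    """Two simulated subjects, shared across read-only tests."""
    return cr.simulate_cohort(2, group_params, seed=777)


def random_com_mixture(rng, max_components=3, allow_delta=True):
    """Random com-space posterior for property tests."""
    k = rng.integers(1, max_components + 1)
    w = rng.dirichlet(np.ones(k))
    means = rng.uniform(-8, 8, k)
    sds = rng.uniform(0.05, 2.0, k)
    if allow_delta and k > 1 and rng.random() < 0.3:
        sds[rng.integers(k)] = 0.0
    return cr.GaussianMixture1D(w, means, sds, space="com")
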