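import numpy as np
import pytest

import paleoniche as pn


@pytest.fixture(scope="session")
def scenario():
    """Small interglacial-like scenario shared across tests."""
    return pn.generate_scenario(50, 50, seed=11)


@pytest.fixture(scope="session")
def scenario_pair(scenario):
    glacial = pn.shift_scenario(
        scenario, pn.glacial_deltas(), seed=12,
        noise_sds=0.3 * pn.default_var_params().sds, label="glacial")
    return scenario, glacial


@pytest.fixture(scope="session")
def true_niche():
    return pn.default_true_niche()


@pytest.fixture(scope="session")
def occurrences(scenario, true_niche):
    return pn.sample_occurrences(scenario, true_niche, 40, seed=13)


@pytest.fixture(scope="session")
def background(scenario):
    env, coords = pn.make_background(scenario, 1500, seed=14)
    return env


@pytest.fixture(scope="session")
def occ_env(scenario, occurrences):
    return pn.extract_values(scenario, occurrences)


@pytest.fixture(scope="session")
def pca(background):
    return pn.fit_pca(background, k=3)


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (no cross-test state)."""
    return np.random.default_rng(2024)
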