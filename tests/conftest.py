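import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_refs():
    from pneumotyper.synth import make_reference_sequences

    return make_reference_sequences(["g_alpha", "g_beta", "g_gamma"], 254, seed=11)


@pytest.fixture(scope="session")
def tiny_sim():
    """A compact full scenario draw (counts only), shared across tests."""
    from pneumotyper.synth import paper_default, simulate_scenario

    scenario = paper_default(
        n_animals=6,
        urt_depth=2000,
        aspirate_depth=1200,
        unique_depth=300,
        environment_depth=1500,
        name="tiny",
    )
    return simulate_scenario(scenario, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_counts(rng):
    n, g = 8, 12
    mat = rng.integers(0, 40, size=(n, g))
    mat[rng.random(mat.shape) < 0.3] = 0
    return pd.DataFrame(
        mat, index=[f"s{i}" for i in range(n)], columns=[f"g{j}" for j in range(g)]
    )
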