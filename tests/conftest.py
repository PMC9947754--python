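import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import geoprobit as gp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lattice44():
    return gp.make_lattice_map(4, 4)


@pytest.fixture(scope="session")
def study_graph():
    """Default 8 x 9 lattice emulating the ~75-district map."""
    return gp.make_lattice_map(8, 9)


@pytest.fixture(scope="session")
def linear_dataset(study_graph):
    """Moderate dataset from the linear-only scenario (known coefficients)."""
    effects = gp.sample_true_effects(study_graph, "linear_only", seed=7)
    ds = gp.simulate_dataset(study_graph, effects, n=1500, seed=8)
    return ds, effects


@pytest.fixture(scope="session")
def small_fit(study_graph, linear_dataset):
    """A short linear-model fit shared by summary/diagnostic tests."""
    from geoprobit.recovery import fit_linear_model

    ds, _effects = linear_dataset
    cfg = gp.SamplerConfig(iterations=900, burnin=300, thin=2, seed=5)
    return fit_linear_model(ds, study_graph, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
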