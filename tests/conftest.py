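import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from ampbias.compositions import make_contrast_matrix
from ampbias.inference import fit_mln
from ampbias.synthetic import mock_community_study


@pytest.fixture(scope="session")
def alr3():
    return make_contrast_matrix("alr", 3)


@pytest.fixture(scope="session")
def small_study():
    """A small but realistic calibration study: 5 taxa, 4 communities."""
    return mock_community_study(seed=7, n_taxa=5, n_communities=4, depth=2000)


@pytest.fixture(scope="session")
def small_fit(small_study):
    s = small_study
    return fit_mln(s.counts, s.design, psi=s.psi, n_draws=300, seed=7)


def random_composition(rng, d):
    return rng.dirichlet(np.ones(d))
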