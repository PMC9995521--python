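import numpy as np
import pytest

from beeal.network import NetworkSpec, build_network
from beeal.odours import OdourProfile, gaussian_k1_profile


@pytest.fixture(scope="session")
def tiny_spec():
    """Reduced AL for fast tests: 6 glomeruli, 78 neurons."""
    return NetworkSpec(
        n_glo=6, n_orn_per_type=8, n_pn_per_glo=2, n_ln_per_glo=3,
        fan_in=4, wiring_seed=42,
    )


@pytest.fixture(scope="session")
def tiny_net(tiny_spec):
    return build_network(tiny_spec)


def narrow_odour(n_glo, center, *, name="test", eta=1.5, sigma=1.5, k2=0.02,
                 permutation=None):
    """Deterministic unscrambled test odorant."""
    perm = np.arange(n_glo) if permutation is None else permutation
    return OdourProfile(
        name=name, k1=gaussian_k1_profile(eta, sigma, center, n_glo)[perm],
        k2=k2, eta=eta, sigma=sigma, center=center, permutation=perm,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
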