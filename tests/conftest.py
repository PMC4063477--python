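import numpy as np
import pytest

from antguild.patch_dynamics import Microhabitat, win_matrix
from antguild.synthetic_data import default_traits, load_fixture_phenologies


@pytest.fixture(scope="session")
def curves():
    return load_fixture_phenologies()


@pytest.fixture(scope="session")
def traits():
    return default_traits()


@pytest.fixture(scope="session")
def strict_W():
    return win_matrix([1, 2, 3], "strict")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_microhabitat(rng, lam_s=(1.0, 200.0), lam_c=(0.5, 200.0)):
    """A positive-parameter microhabitat draw for dynamics tests."""
    return Microhabitat(
        lambda_s=rng.uniform(*lam_s),
        lambda_c=rng.uniform(*lam_c),
        eps_prime=rng.uniform(0.1, 2.0),
        b=rng.uniform(0.1, 0.2),
    )
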