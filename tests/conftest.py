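import pytest

from genfilter import builtin_model
from genfilter.fixtures import (kingman_fixture, lbd_fixture,
                                moran_serial_fixture, seirs_fixture)

# one SEIRS study fixture shared by the filter, SMC and acceptance tests:
# a small closed epidemic with incubation, observed through 3-4 sequenced
# cases over 2.5 time units
SEIRS_PARAMS = dict(N=16, beta=2.5, sigma=2.0, gamma=1.0, psi=0.3,
                    omega=0.5, I0=2, horizon=2.5)


@pytest.fixture(scope="session")
def seirs_case():
    return seirs_fixture(1, min_samples=3, max_samples=4, **SEIRS_PARAMS)


@pytest.fixture(scope="session")
def moran_serial_case():
    return moran_serial_fixture(5, n=6, mu=1.0, psi=0.9, min_samples=2)


@pytest.fixture(scope="session")
def kingman_case():
    return kingman_fixture(3, n=7, mu=2.0, m_samples=4)


@pytest.fixture(scope="session")
def lbd_case():
    return lbd_fixture(11, lam=1.2, mu=0.6, psi=0.4, rho=0.7, x0=2,
                       min_samples=2)


@pytest.fixture(scope="session")
def moran_model():
    return builtin_model("moran", {"n": 6, "mu": 1.0, "psi": 0.9})
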