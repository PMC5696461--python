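import numpy as np
import pytest

import hcgate as hg
from hcgate import reference as ref


@pytest.fixture(scope="session")
def ctx():
    return hg.DEFAULT_CTX


@pytest.fixture(scope="session")
def mlv():
    """Published most-likely parameter vector of the six-site model."""
    return ref.CX46_MLV


@pytest.fixture(scope="session")
def boltz():
    """Published Boltzmann activation parameters of the G-V curve."""
    return hg.BoltzmannParams(v_half=-18.0, z_delta=2.8)


@pytest.fixture(scope="session")
def default_study():
    """One seeded synthetic study at the default conditions."""
    return hg.make_study(seed=11)


def hill_inhibition_curve(ic50=0.17, n=2.0, sd=0.02, seed=1, v_test=0.0,
                          ca=None):
    """Synthetic Hill inhibition curve over the experimental Ca range."""
    rng = np.random.default_rng(seed)
    if ca is None:
        ca = np.logspace(np.log10(0.01), np.log10(1.1), 8)
    y = 1.0 / (1.0 + (ca / ic50) ** n) + rng.normal(0.0, sd, ca.size)
    return hg.InhibitionCurve(v_test, ca, y, np.full(ca.size, sd))
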