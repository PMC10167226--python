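import numpy as np
import pytest

import loopchap as lc


@pytest.fixture(scope="session")
def kd_scale():
    return lc.load_scale("kyte_doolittle")


@pytest.fixture(scope="session")
def bio_scale():
    return lc.load_scale("biological")


@pytest.fixture()
def rng():
    return np.random.default_rng(20230508)


@pytest.fixture()
def logistic_trace():
    """A clean saturating turbidity trace on the 90 s plate cadence."""
    t = np.arange(0.0, 3600.0 + 1, 90.0)
    y = 0.5 / (1.0 + np.exp((1800.0 - t) / 300.0))
    return lc.AggregationTrace(times=t, signal=y, substrate="CS")


def random_valid_params(rng, kappa_decades=(-4.5, -2.5), ratio_decades=(-2.0, 0.0)):
    """KineticParams with κ and λ/κ drawn log-uniformly from the given boxes."""
    m0, n_c, n_2, k_plus = 3e-6, 2.0, 2.0, 3e6
    kappa = 10.0 ** rng.uniform(*kappa_decades)
    lam = kappa * 10.0 ** rng.uniform(*ratio_decades)
    k_n = lam**2 / (2.0 * k_plus * m0**n_c)
    k_2 = kappa**2 / (2.0 * k_plus * m0 ** (n_2 + 1))
    return lc.KineticParams(k_n=k_n, k_plus=k_plus, k_2=k_2, n_c=n_c, n_2=n_2, m0=m0)
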