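import numpy as np
import pytest

from pairsel import (ChainSettings, PairedDesign, PriorSpec, run_chain)


@pytest.fixture(scope="session")
def toy_design():
    """Small paired design with one informative intensity (pair 2 of 3)."""
    rng = np.random.default_rng(42)
    n = 60
    U = rng.normal(0, 1, (n, 3))
    V = rng.normal(0, 1, (n, 3))
    eta = 2.0 * U[:, 1]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return PairedDesign(y, U, V)


@pytest.fixture(scope="session")
def short_chain(toy_design):
    """A short but real fitted chain used by summary/oracle tests."""
    settings = ChainSettings(n_iter=4000, burn_in=1000, thin=5, seed=11)
    return run_chain(toy_design, PriorSpec(kmax=3), settings)
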