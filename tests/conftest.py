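import numpy as np
import pytest

import helixscan as hx
from helixscan.cg_model import variant_parameters


@pytest.fixture(scope="session")
def default_windows():
    return hx.build_windows(12, 0.0, 0.5, 1000.0)


@pytest.fixture(scope="session")
def hremd_samples(default_windows):
    """One moderately long replica-exchange run on a mixed helix-prone
    10-mer, shared across tests that only read it."""
    params = variant_parameters("V-TIP3P", sequence="ARLREALKAQ")
    return hx.run_hremd(
        params, default_windows, n_steps=2500, exchange_interval=100, seed=7
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_chain(rng, n=10):
    """Random valid Cα-trace conformation via internal coordinates."""
    from helixscan import geometry
    from helixscan.cg_model import BOND_LENGTH, ChainConformation

    angles = np.deg2rad(91.0) + rng.normal(0.0, 0.08, n - 2)
    dihs = rng.uniform(-np.pi, np.pi, n - 3)
    return ChainConformation(geometry.build_chain(BOND_LENGTH, angles, dihs))
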