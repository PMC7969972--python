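import numpy as np
import pytest

from drsix.chromophores import ChromophoreTable
from drsix.mc import LUT, MCConfig, build_lut, default_axes


@pytest.fixture(scope="session")
def chromo():
    return ChromophoreTable.default()


@pytest.fixture(scope="session")
def toy_lut():
    """Analytic, noise-free LUT on the study axes: monotone decreasing in mua,
    increasing in mus'.  Lets interpolation/forward/inverse tests run without
    Monte Carlo noise or cost."""
    ax = default_axes()
    mua, musp = np.meshgrid(ax, ax, indexing="ij")
    R = 0.9 * np.exp(-mua / 40.0) * musp / (musp + 15.0)
    return LUT(ax, ax, R, meta={"mode": "analytic"})


@pytest.fixture(scope="session")
def mc_lut():
    """A real (reduced-photon) Monte Carlo LUT shared across tests."""
    return build_lut(cfg=MCConfig(n_photons=20_000, seed=123))
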