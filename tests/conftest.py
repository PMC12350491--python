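import numpy as np
import pytest

from lungdce.aif import AifSpec
from lungdce.synthetic import default_acquisition, generate_phantom, render_dce

FAST_FRAME_MIN = 1.34 / 60.0  # fast-phase frame spacing in minutes


@pytest.fixture(scope="session")
def acq():
    return default_acquisition()


@pytest.fixture(scope="session")
def georgiou():
    return AifSpec("georgiou")


@pytest.fixture(scope="session")
def tic_factory(acq, georgiou):
    """Render a mean-tumor TIC from a small phantom with a known bolus delay."""

    def make(seed: int, t0_true: float, noisy: bool = True, group: str = "hypo"):
        phantom = generate_phantom(
            (8, 8, 2), group, np.random.default_rng(seed), t0_true=t0_true,
            necrotic_fraction=0.0,
        )
        a = acq if noisy else acq.with_(noise_sigma=0.0)
        series = render_dce(phantom, a, georgiou, np.random.default_rng(seed + 10_000))
        return series.mean_tumor_tic(phantom.tumor_mask)

    return make
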