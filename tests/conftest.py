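import numpy as np
import pytest

from qpcmr import AifModelParams, KineticParams, gamma_variate_aif


@pytest.fixture(scope="session")
def time_grid():
    """60 s acquisition, one frame per second."""
    return np.arange(0.0, 60.0, 1.0)


@pytest.fixture(scope="session")
def aif(time_grid):
    """Default first-pass AIF with recirculation, ~5 mM blood peak."""
    return gamma_variate_aif(AifModelParams(), time_grid)


@pytest.fixture(scope="session")
def model_truths():
    """One interior-of-bounds generating parameter set per kinetic model."""
    return {
        "tofts": KineticParams(model="tofts", ktrans=0.8, ve=0.15, delay=2.0),
        "modified_tofts": KineticParams(
            model="modified_tofts", ktrans=0.8, ve=0.15, vp=0.05, delay=2.0
        ),
        "fermi": KineticParams(model="fermi", f=3.0, k=0.4, mtt=6.0, delay=2.0),
    }
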