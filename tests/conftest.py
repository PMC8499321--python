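import numpy as np
import pytest

from pantoea_abm.config import ParameterSet
from pantoea_abm.growth import PopulationCurve, logistic_model


@pytest.fixture
def default_params():
    return ParameterSet()


@pytest.fixture
def small_params():
    """A light configuration: coarse grid via patch_side, short world."""
    return ParameterSet(
        umax_pa=5.0,
        steptime=0.6,
        diffusion_coefficient=0.2,
        pmax=4,
        glucose=20.0,
        depth=20.0,
        microorganism=50,
    )


def make_logistic_curve(A=300.0, mu=6.0, tau=2.5, t_max=18.0, dt=1.0, noise_sd=0.0, seed=0):
    t = np.arange(0.0, t_max + 1e-9, dt)
    y = logistic_model(t, A, mu, tau)
    if noise_sd:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
    y = np.clip(np.round(y), 0, None).astype(int) if noise_sd else y
    return PopulationCurve(time_h=t, population=np.asarray(y))


@pytest.fixture
def logistic_curve_factory():
    return make_logistic_curve
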