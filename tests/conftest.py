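import numpy as np
import pytest

from cestkit.axis import default_axis
from cestkit.lorentzfit import model_pools
from cestkit.pools import default_pools
from cestkit.synthetic import PhantomConfig, default_region_layout

#: canonical five-pool truth used across recovery tests
TRUTH_A = {"water": 0.85, "mt": 0.08, "creatine": 0.04, "glutamate": 0.05, "noe": 0.06}
TRUTH_G = {"water": 1.4, "mt": 3.0, "creatine": 1.0, "glutamate": 1.2, "noe": 2.5}


def truth_pools(a=None, g=None):
    a = a or TRUTH_A
    g = g or TRUTH_G
    return [p.with_values(amplitude=a[p.name], fwhm=g[p.name]) for p in default_pools()]


@pytest.fixture(scope="session")
def axis():
    return default_axis()


@pytest.fixture(scope="session")
def clean_spectrum(axis):
    return model_pools(truth_pools(), axis)


def tiny_config(seed: int = 0, noise: float = 0.005) -> PhantomConfig:
    """Small study (2 subjects/arm, 16x16 grid) for fast end-to-end tests."""
    grid = (16, 16)
    return PhantomConfig(
        grid_shape=grid,
        region_layout=default_region_layout(grid, block=(3, 3)),
        n_subjects_per_arm={"baseline": 2, "wk6": 2, "wk12_vehicle": 2, "wk12_art": 2},
        noise_sigma=noise,
        wassr_noise_sigma=noise,
        seed=seed,
    )
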