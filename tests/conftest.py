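"""Shared fixtures: desk-scale optics and cached PSF simulators.

Wave-optics PSF simulation is the expensive step, so simulators (which
cache sensor patches per depth) are session-scoped and shared.
"""

import numpy as np
import pytest

from qlfm import (
    PSFSimulator,
    preset_20x_na05,
    preset_40x_na1,
    uniform_grid,
)
from qlfm.projection import psf_for_grid


@pytest.fixture(scope="session")
def desk_config():
    """x20/0.5 NA desk-scale geometry: 15x15 lenses, 13x13 px per lens."""
    return preset_20x_na05()


@pytest.fixture(scope="session")
def config_40x():
    return preset_40x_na1()


@pytest.fixture(scope="session")
def sim_full(desk_config):
    """Unbinned simulator (13x13 angular components)."""
    return PSFSimulator(desk_config)


@pytest.fixture(scope="session")
def sim5(sim_full):
    """5x5 angularly binned simulator sharing the patch cache."""
    return sim_full.rebinned(5)


@pytest.fixture(scope="session")
def fine_grid(desk_config):
    """Single fine slab +-30 um at lens-pitch sampling."""
    step0 = desk_config.lens_pitch_sample
    return uniform_grid(
        -30.0, 30.0, 12.0, step0, desk_config.num_lenses,
        lens_pitch_sample=step0, num_lenses=desk_config.num_lenses,
    )


@pytest.fixture(scope="session")
def fine_psf(sim5, fine_grid):
    return psf_for_grid(sim5, fine_grid)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
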