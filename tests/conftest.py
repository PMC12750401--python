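import math

import numpy as np
import pytest

import sptcal as sc
from sptcal.pipeline import detect_once, simulate_stack


@pytest.fixture(scope="session")
def small_fixture():
    """60-frame reference-condition movie (D = 11, 0.035 um^-2)."""
    optical = sc.OpticalTimingConfig(n_frames=60)
    sample = sc.SampleConfig(diffusion_um2_s=11.0, density_um2=0.035,
                             seed=11, replenish=True)
    stack, truth = simulate_stack(sample, optical, sc.EmitterModel(), seed=11)
    return stack, truth


@pytest.fixture(scope="session")
def small_spots(small_fixture):
    stack, _ = small_fixture
    spots, sigma_loc = detect_once(stack, d_hint_um2_s=11.0)
    return spots, sigma_loc


@pytest.fixture(scope="session")
def immobile_stack():
    """Bright immobile emitters for localization calibration."""
    optical = sc.OpticalTimingConfig(n_frames=40)
    pos = tuple((x, y) for x in (-8.0, 0.0, 8.0) for y in (-6.0, 6.0))
    sample = sc.SampleConfig(diffusion_um2_s=0.0, density_um2=0.0,
                             seed=13, init_positions_um=pos)
    emitter = sc.EmitterModel(bleach_mean_photons=math.inf)
    stack, truth = simulate_stack(sample, optical, emitter, seed=13)
    return stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
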