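"""Simulator: Brownian statistics, rendering photometry, confocal traces."""

import hashlib
import math

import numpy as np
import pytest

import sptcal as sc
from sptcal.simulate import (SimulationSizeError, render_stack,
                             simulate_confocal_trace, simulate_positions)


def _wrapped_increments(truth):
    """Minimum-image increments of the periodic walk."""
    d = np.diff(truth.positions, axis=0)
    L = truth.domain_um
    return (d + L / 2) % L - L / 2


def test_zero_diffusion_positions_are_constant():
    optical = sc.OpticalTimingConfig(n_frames=5)
    sample = sc.SampleConfig(diffusion_um2_s=0.0, density_um2=0.0,
                             n_particles=7, seed=1)
    truth = simulate_positions(sample, optical, substeps_per_frame=4)
    assert np.all(truth.positions == truth.positions[0])


def test_increment_variance_matches_2_d_dt():
    """Pooled moment estimator on the generated increments recovers D."""
    d_true = 5.0
    optical = sc.OpticalTimingConfig(n_frames=200)
    sample = sc.SampleConfig(diffusion_um2_s=d_true, density_um2=0.0,
                             n_particles=200, seed=2)
    truth = simulate_positions(sample, optical, substeps_per_frame=10)
    incr = _wrapped_increments(truth)
    dts = np.diff(truth.times_s)[:, None, None]
    d_hat = (incr ** 2 / (2 * dts)).mean()
    n = incr.size
    se = d_hat * math.sqrt(2.0 / n)
    assert abs(d_hat - d_true) < 3 * se


def test_expected_in_disc_count_matches_density():
    """density * illuminated area ~ 38.5 emitters at 0.035 um^-2."""
    optical = sc.OpticalTimingConfig(n_frames=1)
    counts = []
    for seed in range(25):
        sample = sc.SampleConfig(diffusion_um2_s=1.0, density_um2=0.035,
                                 seed=seed)
        truth = simulate_positions(sample, optical, substeps_per_frame=1)
        r2 = (truth.positions[0] ** 2).sum(axis=1)
        counts.append((r2 < optical.mask_radius_um ** 2).sum())
    assert 0.035 * 1100.0 == pytest.approx(38.5, abs=0.1)   # the ~1100 um^2 disc
    expected = 0.035 * optical.illuminated_area_um2
    se = math.sqrt(expected / len(counts))
    assert abs(np.mean(counts) - expected) < 3.5 * se


def test_particle_cap_raises():
    optical = sc.OpticalTimingConfig(n_frames=1)
    sample = sc.SampleConfig(diffusion_um2_s=1.0, density_um2=0.0,
                             n_particles=100, seed=0)
    with pytest.raises(SimulationSizeError):
        simulate_positions(sample, optical, max_particles=50)


def test_render_photon_conservation_at_beam_centre():
    """One emitter at the mask centre: mean signal = rate * exposure."""
    optical = sc.OpticalTimingConfig(n_frames=30)
    sample = sc.SampleConfig(diffusion_um2_s=0.0, density_um2=0.0,
                             init_positions_um=((0.0, 0.0),), seed=3)
    emitter = sc.EmitterModel(peak_photon_rate=5000.0,
                              bleach_mean_photons=math.inf,
                              background_rate=0.0, read_noise_sd=0.0)
    truth = simulate_positions(sample, optical)
    stack = render_stack(truth, optical, emitter, seed=3)
    per_frame = stack.data.sum(axis=(1, 2)).astype(float)
    expected = emitter.peak_photon_rate * optical.exposure_s
    se = math.sqrt(expected / len(per_frame))
    assert abs(per_frame.mean() - expected) < 4 * se


def test_emitter_outside_mask_is_dark():
    optical = sc.OpticalTimingConfig(n_frames=5)
    sample = sc.SampleConfig(diffusion_um2_s=0.0, density_um2=0.0,
                             init_positions_um=((20.0, 0.0),), seed=4)
    emitter = sc.EmitterModel(background_rate=0.0, read_noise_sd=0.0,
                              bleach_mean_photons=math.inf)
    truth = simulate_positions(sample, optical)
    stack = render_stack(truth, optical, emitter, seed=4)
    assert stack.data.sum() == 0


def test_bleach_lifetime_is_budget_over_rate():
    """Exponential photon budget: mean emitting lifetime = B / R."""
    rate, budget = 5000.0, 500.0
    optical = sc.OpticalTimingConfig(n_frames=60)
    pos = tuple((0.0, 0.0) for _ in range(60))
    sample = sc.SampleConfig(diffusion_um2_s=0.0, density_um2=0.0,
                             init_positions_um=pos, seed=5)
    emitter = sc.EmitterModel(peak_photon_rate=rate, bleach_mean_photons=budget,
                              background_rate=0.0, read_noise_sd=0.0)
    truth = simulate_positions(sample, optical)
    render_stack(truth, optical, emitter, seed=5)
    lifetimes = truth.bleach_time_s[:60]
    assert np.all(np.isfinite(lifetimes))
    expected = budget / rate
    se = expected / math.sqrt(len(lifetimes))
    assert abs(lifetimes.mean() - expected) < 3.5 * se


def test_bleaching_without_replenish_dims_the_field():
    optical = sc.OpticalTimingConfig(n_frames=80)
    sample = sc.SampleConfig(diffusion_um2_s=2.0, density_um2=0.035, seed=6)
    emitter = sc.EmitterModel(bleach_mean_photons=2000.0)
    truth = simulate_positions(sample, optical)
    render_stack(truth, optical, emitter, seed=6)
    photons = truth.frame_photons.sum(axis=1).astype(float)
    assert photons[:20].mean() > 3 * photons[-20:].mean()


def test_replenish_keeps_emitting_density_stationary():
    optical = sc.OpticalTimingConfig(n_frames=120)
    sample = sc.SampleConfig(diffusion_um2_s=11.0, density_um2=0.035,
                             seed=7, replenish=True)
    emitter = sc.EmitterModel()
    truth = simulate_positions(sample, optical)
    render_stack(truth, optical, emitter, seed=7)
    emitting = (truth.frame_photons > 30).sum(axis=1).astype(float)
    first, last = emitting[:30].mean(), emitting[-30:].mean()
    assert last > 0.7 * first


def test_confocal_background_is_poisson():
    optical = sc.OpticalTimingConfig(n_frames=1, dwell_us=10.0)
    sample = sc.SampleConfig(diffusion_um2_s=1.0, density_um2=0.0,
                             n_particles=0, seed=8)
    trace = simulate_confocal_trace(sample, optical, duration_s=2.0,
                                    background_hz=5000.0, seed=8)
    mean = trace.counts.mean()
    assert mean == pytest.approx(5000.0 * 10e-6, rel=0.05)
    assert trace.counts.var() == pytest.approx(mean, rel=0.1)


def test_confocal_immobile_particle_constant_mean():
    optical = sc.OpticalTimingConfig(n_frames=1, dwell_us=10.0)
    sample = sc.SampleConfig(diffusion_um2_s=0.0, density_um2=0.0,
                             init_positions_um=((0.0, 0.0),), seed=9)
    trace = simulate_confocal_trace(sample, optical, duration_s=2.0,
                                    background_hz=0.0, seed=9)
    half = len(trace.counts) // 2
    rate = 5.0e4 * 10e-6
    assert trace.counts[:half].mean() == pytest.approx(rate, rel=0.05)
    assert trace.counts[half:].mean() == pytest.approx(rate, rel=0.05)


def test_short_trace_warns():
    optical = sc.OpticalTimingConfig(n_frames=1, dwell_us=10.0)
    sample = sc.SampleConfig(diffusion_um2_s=1.0, density_um2=0.01, seed=10)
    with pytest.warns(UserWarning, match="100 crossing"):
        simulate_confocal_trace(sample, optical, duration_s=0.1, seed=10)


def test_fixture_generation_is_bit_deterministic():
    h = []
    for _ in range(2):
        bundle = sc.make_fixture("reference-bilayer", seed=1, n_frames=12,
                                 confocal_duration_s=0.5)
        digest = hashlib.sha256(bundle.stack.data.tobytes())
        digest.update(bundle.trace.counts.tobytes())
        h.append(digest.hexdigest())
    assert h[0] == h[1]


def test_unknown_fixture_name():
    with pytest.raises(KeyError):
        sc.make_fixture("nope", seed=1)
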