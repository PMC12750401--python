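"""Spot detection, LAP linking, localization-uncertainty estimation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sptcal as sc
from sptcal.pipeline import simulate_stack
from sptcal.tracking import (apparent_density, detect_params_for,
                             detect_spots, estimate_localization_sigma,
                             link_spots)


def _spots_df(rows):
    """rows: (frame, x, y) or (frame, x, y, intensity)."""
    rows = [r if len(r) == 4 else (*r, 100.0) for r in rows]
    return pd.DataFrame(rows, columns=["frame", "x_um", "y_um", "intensity"])


def _render_points(points_um, n_frames=20, rate=2.0e4, seed=0, d=0.0):
    optical = sc.OpticalTimingConfig(n_frames=n_frames)
    sample = sc.SampleConfig(diffusion_um2_s=d, density_um2=0.0,
                             init_positions_um=tuple(points_um), seed=seed)
    emitter = sc.EmitterModel(peak_photon_rate=rate,
                              bleach_mean_photons=math.inf)
    return simulate_stack(sample, optical, emitter, seed=seed)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def test_background_only_stack_yields_no_spots():
    stack, _ = _render_points([], n_frames=10)
    spots = detect_spots(stack)
    assert len(spots) == 0
    assert spots.attrs["n_frames"] == 10


def test_single_emitter_localized_within_50_nm():
    stack, truth = _render_points([(1.23, -2.31)], n_frames=25)
    spots = detect_spots(stack)
    assert spots.groupby("frame").size().max() == 1
    fp = truth.frame_positions
    err = np.hypot(spots["x_um"] - fp[spots["frame"], 0, 0],
                   spots["y_um"] - fp[spots["frame"], 0, 1])
    assert err.mean() < 0.050


def test_two_emitters_five_psf_radii_apart_resolved():
    sep = 5 * 0.280   # 5x the PSF radius
    stack, _ = _render_points([(-sep / 2, 0.0), (sep / 2, 0.0)], n_frames=15)
    spots = detect_spots(stack)
    per_frame = spots.groupby("frame").size()
    assert (per_frame == 2).all()


def test_detection_recall_and_false_positives_on_fixture():
    """>=95% recall on resolvable bright emitters, <=2% spurious spots."""
    optical = sc.OpticalTimingConfig(n_frames=30)
    sample = sc.SampleConfig(diffusion_um2_s=1.0, density_um2=0.02,
                             seed=9, replenish=True)
    stack, truth = simulate_stack(sample, optical, sc.EmitterModel(), seed=9)
    spots = detect_spots(stack, **detect_params_for(optical, 1.0))
    fp = np.nan_to_num(truth.frame_positions, nan=1e6)
    ph = truth.frame_photons
    match_r = 1.5 * optical.pixel_um
    hits = total = false = 0
    for f in range(stack.n_frames):
        det = spots[spots["frame"] == f][["x_um", "y_um"]].to_numpy()
        r = np.hypot(fp[f, :, 0], fp[f, :, 1])
        visible = np.flatnonzero((ph[f] > 100)
                                 & (r < 0.8 * optical.mask_radius_um))
        for j in visible:
            others = np.flatnonzero(ph[f] > 30)
            others = others[others != j]
            nn = np.hypot(*(fp[f, others] - fp[f, j]).T).min() \
                if len(others) else np.inf
            if nn < 1.0:      # unresolvable pair: excluded by construction
                continue
            total += 1
            if len(det) and np.hypot(det[:, 0] - fp[f, j, 0],
                                     det[:, 1] - fp[f, j, 1]).min() < match_r:
                hits += 1
        emitters = np.flatnonzero(ph[f] > 10)
        if len(det) and len(emitters):
            d = np.hypot(det[:, 0, None] - fp[f, emitters, 0][None],
                         det[:, 1, None] - fp[f, emitters, 1][None])
            false += (d.min(axis=1) > 2 * match_r).sum()
    assert hits / total >= 0.95
    assert false / len(spots) <= 0.02


def test_detect_params_track_motion_blur():
    optical = sc.OpticalTimingConfig()
    slow = detect_params_for(optical, 1.0)
    fast = detect_params_for(optical, 11.0)
    assert fast["detect_sigma_px"] > slow["detect_sigma_px"]
    assert fast["window_radius"] >= slow["window_radius"]


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def test_sub_mlr_motion_yields_one_unbroken_trajectory():
    spots = _spots_df([(f, 0.5 * f, 0.0) for f in range(6)])
    ts = link_spots(spots, sc.LinkConfig(mlr_um=2.3))
    assert ts.n_tracks == 1
    assert len(ts.df) == 6


def test_jump_beyond_mlr_splits_the_trajectory():
    spots = _spots_df([(0, 0.0, 0.0), (1, 0.1, 0.0), (2, 3.1, 0.0),
                       (3, 3.2, 0.0)])
    ts = link_spots(spots, sc.LinkConfig(mlr_um=2.3))
    assert ts.n_tracks == 2
    lengths = sorted(ts.df.groupby("track_id").size())
    assert lengths == [2, 2]


def test_two_particle_assignment_matches_brute_force():
    """LAP picks the pairing with minimal total squared displacement."""
    p1 = [(0.0, 0.0), (2.0, 0.0)]
    p2 = [(1.1, 0.0), (2.9, 0.0)]
    costs = []
    for perm in ([0, 1], [1, 0]):
        costs.append(sum((p1[i][0] - p2[perm[i]][0]) ** 2 for i in range(2)))
    best = np.argmin(costs)
    assert best == 0    # (0->1.1, 2->2.9) is cheaper by hand
    spots = _spots_df([(0, *p1[0]), (0, *p1[1]), (1, *p2[0]), (1, *p2[1])])
    ts = link_spots(spots, sc.LinkConfig(mlr_um=2.3))
    track_of_origin = ts.df[(ts.df["frame"] == 0) & (ts.df["x_um"] == 0.0)
                            ]["track_id"].iloc[0]
    partner = ts.df[(ts.df["track_id"] == track_of_origin)
                    & (ts.df["frame"] == 1)]["x_um"].iloc[0]
    assert partner == pytest.approx(1.1)


def _total_cost(ts, spots, mlr):
    steps = ts.steps()
    linked = len(steps)
    opened = len(spots) - linked  # every unlinked end is a birth or death
    return steps["sd_um2"].sum() + mlr ** 2 * opened


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_linking_cost_invariant_to_spot_order(seed):
    rng = np.random.default_rng(seed)
    frames = np.repeat([0, 1], [8, 8])
    xy = rng.uniform(-5, 5, size=(16, 2))
    spots = pd.DataFrame({"frame": frames, "x_um": xy[:, 0],
                          "y_um": xy[:, 1], "intensity": 1.0})
    perm = np.concatenate([rng.permutation(8), 8 + rng.permutation(8)])
    shuffled = spots.iloc[perm].reset_index(drop=True)
    cfg = sc.LinkConfig(mlr_um=3.0)
    c1 = _total_cost(link_spots(spots, cfg, min_track_len=1), spots, 3.0)
    c2 = _total_cost(link_spots(shuffled, cfg, min_track_len=1), shuffled, 3.0)
    assert c1 == pytest.approx(c2, rel=1e-9)


@settings(deadline=None, max_examples=15, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_link_count_nondecreasing_in_mlr(seed):
    rng = np.random.default_rng(seed)
    rows = []
    for f in range(5):
        for _ in range(rng.integers(3, 9)):
            rows.append((f, *rng.uniform(-6, 6, 2)))
    spots = _spots_df(rows)
    links = []
    for mlr in (0.5, 1.0, 2.0, 4.0, 8.0):
        ts = link_spots(spots, sc.LinkConfig(mlr_um=mlr), min_track_len=1)
        links.append(len(ts.steps()))
    assert all(a <= b for a, b in zip(links, links[1:]))


def test_max_step_never_exceeds_mlr(small_spots):
    spots, _ = small_spots
    for mlr in (1.0, 2.3):
        ts = link_spots(spots, sc.LinkConfig(mlr_um=mlr))
        if len(ts.df):
            assert ts.steps()["sd_um2"].max() <= mlr ** 2 + 1e-9


def test_single_particle_tracking_oracle():
    """At infinite dilution and high SNR the trajectory is exact."""
    stack, truth = _render_points([(0.0, 0.0)], n_frames=60, d=1.0, seed=5)
    spots = detect_spots(stack, **detect_params_for(stack.optical, 1.0))
    mlr = 3 * math.sqrt(4 * 1.0 * 0.042)
    ts = link_spots(spots, sc.LinkConfig(mlr_um=mlr))
    assert ts.n_tracks == 1
    track = ts.df.sort_values("frame")
    assert list(track["frame"]) == list(range(60))
    fp = truth.frame_positions
    err = np.hypot(track["x_um"] - fp[:, 0, 0], track["y_um"] - fp[:, 0, 1])
    assert err.mean() < 0.10          # typical localization well under a pixel
    assert err.max() < 0.50           # rare smear-shape outliers stay bounded


# ---------------------------------------------------------------------------
# localization sigma and apparent density
# ---------------------------------------------------------------------------

def test_empirical_sigma_matches_ground_truth_residuals(immobile_stack):
    stack, truth = immobile_stack
    est = estimate_localization_sigma(stack=stack)
    assert est.method == "empirical"
    spots = detect_spots(stack)
    fp = truth.frame_positions[0]
    resid = []
    for _, row in spots.iterrows():
        j = np.argmin(np.hypot(fp[:, 0] - row.x_um, fp[:, 1] - row.y_um))
        resid.extend([row.x_um - fp[j, 0], row.y_um - fp[j, 1]])
    truth_sd = np.std(resid)
    assert est.sigma_um == pytest.approx(truth_sd, rel=0.35)


def test_sigma_scales_as_inverse_sqrt_photons():
    def sigma_at(rate, seed):
        pos = tuple((x, y) for x in (-8.0, 0.0, 8.0) for y in (-6.0, 6.0))
        optical = sc.OpticalTimingConfig(n_frames=40)
        sample = sc.SampleConfig(diffusion_um2_s=0.0, density_um2=0.0,
                                 init_positions_um=pos, seed=seed)
        emitter = sc.EmitterModel(peak_photon_rate=rate,
                                  bleach_mean_photons=math.inf)
        stack, _ = simulate_stack(sample, optical, emitter, seed=seed)
        return estimate_localization_sigma(stack=stack).sigma_um

    s1 = sigma_at(3000.0, 17)
    s4 = sigma_at(12000.0, 18)
    assert s4 == pytest.approx(s1 / 2, rel=0.25)


def test_high_snr_noiseless_sigma_is_tiny():
    stack, _ = _render_points([(0.0, 0.0)], n_frames=40, rate=1.0e5, seed=6)
    est = estimate_localization_sigma(stack=stack)
    assert est.sigma_um < 0.012


def test_apparent_density_arithmetic():
    spots = pd.DataFrame({"frame": np.repeat(np.arange(10), 38),
                          "x_um": 0.0, "y_um": 0.0})
    assert apparent_density(spots, 1100.0, n_frames=10) == \
        pytest.approx(0.03454, abs=1e-4)
    empty = pd.DataFrame(columns=["frame", "x_um", "y_um"])
    assert apparent_density(empty, 1100.0, n_frames=5) == 0.0
    with pytest.raises(ValueError):
        apparent_density(spots, 0.0, n_frames=10)


def test_crowding_undercounts_apparent_density():
    optical = sc.OpticalTimingConfig(n_frames=20)
    sample = sc.SampleConfig(diffusion_um2_s=11.0, density_um2=0.125, seed=19)
    emitter = sc.EmitterModel(bleach_mean_photons=math.inf)
    stack, _ = simulate_stack(sample, optical, emitter, seed=19)
    spots = detect_spots(stack, **detect_params_for(optical, 11.0))
    dens = apparent_density(spots, optical.illuminated_area_um2,
                            n_frames=stack.n_frames)
    assert dens < 0.110
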