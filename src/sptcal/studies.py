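"""Pre-assembled end-to-end studies at the reference conditions.

These bundle the full chains used to validate the method:

* :func:`fcs_roundtrip` - 60 s confocal trace at D = 11 um^2 s^-1,
  multiple-tau autocorrelation, 2D-model fit, D from omega_1.
* :func:`calibration_study` - replicate widefield movies of the reference
  bilayer (D = 11, 0.035 um^-2, bleaching with replenishment, EMCCD
  emulation), the MLR sweep with FCS crossing, the SD-histogram kink, the
  plateau diagnostic and the 1.7 -> 8.4 um centroid fold change.
* :func:`accuracy_grid` - the reduced diffusion-accuracy grid (D x density
  x MLR over replicate seeds, no bleaching).

Problem sizes default to desk scale (minutes on one CPU); each function
takes an explicit seed and is deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibrate import CalibrationResult, calibrate
from .config import EmitterModel, OpticalTimingConfig, SampleConfig, TimingInfo
from .errorgrid import ErrorGrid, GridConfig, run_grid
from .fcs import autocorrelate, fit_g2d
from .pipeline import detect_once, simulate_stack
from .simulate import simulate_confocal_trace

__all__ = ["fcs_roundtrip", "calibration_study", "accuracy_grid",
           "CalibrationStudy"]

SWEEP_GRID = (1.0, 1.4, 1.7, 2.0, 2.3, 2.6, 3.0, 3.4, 4.2, 5.0, 5.9, 7.0, 8.4)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


def fcs_roundtrip(seed: int = 1, d_true: float = 11.0,
                  density: float = 0.035, duration_s: float = 60.0) -> dict:
    """Simulate a confocal trace, autocorrelate, fit, and return D."""
    optical = OpticalTimingConfig()
    sample = SampleConfig(diffusion_um2_s=d_true, density_um2=density,
                          seed=seed)
    trace = simulate_confocal_trace(sample, optical, duration_s=duration_s,
                                    seed=seed)
    curve = autocorrelate(trace)
    fit = fit_g2d(curve, omega1_nm=optical.omega1_nm)
    return {"d_fcs_um2_s": fit.D_um2_s, "tau_D_s": fit.tau_D_s,
            "n_mean": fit.n_mean, "ci95": fit.ci95,
            "n_bins": len(trace.counts), "d_true": d_true}


@dataclass
class CalibrationStudy:
    result: CalibrationResult
    fold_change_1p7_to_8p4: float
    d_at_8p4_um2_s: float
    n_frames: int
    n_replicates: int


def calibration_study(seed: int = 1, n_frames: int = 1000,
                      n_replicates: int = 3, d_fcs: float = 11.0,
                      mlr_grid=SWEEP_GRID) -> CalibrationStudy:
    """The reference-bilayer MLR calibration, replicated over seeds.

    Simulates the widefield fixture (D = 11 um^2 s^-1 at 0.035 um^-2 with
    photobleaching, replenishment and EMCCD excess noise), detects once per
    replicate with blur-matched parameters informed by D_fcs, sweeps the
    linker over the MLR grid, and extracts the FCS crossing, the kink and
    the plateau diagnostics.
    """
    optical = OpticalTimingConfig(n_frames=n_frames)
    emitter = EmitterModel(em_excess_noise=True)
    timing = TimingInfo.from_optical(optical)
    spot_sets, sigmas = [], []
    for s in _child_seeds(seed, n_replicates):
        sample = SampleConfig(diffusion_um2_s=11.0, density_um2=0.035,
                              seed=s, replenish=True)
        stack, _ = simulate_stack(sample, optical, emitter, seed=s)
        spots, sig = detect_once(stack, d_hint_um2_s=d_fcs)
        spot_sets.append(spots)
        sigmas.append(sig)
    result = calibrate(spot_sets, mlr_grid, d_fcs, timing, sigma_locs=sigmas)
    grid = list(result.mlr_grid)
    c = result.centroid_log10
    fold = 10.0 ** (c[grid.index(8.4)] - c[grid.index(1.7)])
    return CalibrationStudy(result=result,
                            fold_change_1p7_to_8p4=float(fold),
                            d_at_8p4_um2_s=float(10.0 ** c[grid.index(8.4)]),
                            n_frames=n_frames, n_replicates=n_replicates)


def accuracy_grid(seed: int = 1, n_frames: int = 800,
                  densities=(0.005, 0.035, 0.125),
                  mlrs=(1.0, 2.3, 15.1), n_replicates: int = 3) -> ErrorGrid:
    """The reduced diffusion-accuracy grid used for validation."""
    cfg = GridConfig(densities=tuple(densities), mlrs=tuple(mlrs),
                     n_frames=n_frames, n_replicates=n_replicates)
    return run_grid(cfg, seed=seed)


def grid_error_summary(grid: ErrorGrid) -> dict:
    """Headline error statistics of an accuracy grid.

    ``max_abs_error_at_optimal_pct`` is over cell means at MLR = 2.3 um;
    the min/max errors are over cell means at the nonoptimal MLRs.
    """
    cm = grid.cell_means()
    opt = cm[cm["mlr"] == 2.3]
    non = cm[cm["mlr"] != 2.3]
    return {
        "max_abs_error_at_optimal_pct":
            float(opt["error_mean_pct"].abs().max()),
        "min_error_nonoptimal_pct": float(non["error_mean_pct"].min()),
        "max_error_nonoptimal_pct": float(non["error_mean_pct"].max()),
        "n_cells": int(len(cm)),
    }
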