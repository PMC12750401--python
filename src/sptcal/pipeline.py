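"""Shared simulate -> detect -> link -> estimate plumbing.

The calibration sweep, the accuracy grid and the command-line interface all
run the same chain; these helpers keep the chain in one place and make sure
detection is performed once per stack and reused across linking radii.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (AnalysisConfig, EmitterModel, LinkConfig,
                     OpticalTimingConfig, SampleConfig, TimingInfo)
from .diffusion import estimates_table, fit_lognormal_centroid
from .simulate import GroundTruth, ImageStack, render_stack, simulate_positions
from .tracking import (detect_params_for, detect_spots,
                       estimate_localization_sigma, link_spots)

__all__ = ["simulate_stack", "detect_once", "centroid_at_mlrs", "CellResult"]


def simulate_stack(sample: SampleConfig, optical: OpticalTimingConfig,
                   emitter: EmitterModel, seed: int,
                   substeps_per_frame: int = 10,
                   margin_um: float = 20.0) -> tuple[ImageStack, GroundTruth]:
    """Simulate trajectories and render the widefield movie in one call."""
    ss = np.random.SeedSequence(seed)
    s_pos, s_render = ss.spawn(2)
    truth = simulate_positions(sample, optical,
                               substeps_per_frame=substeps_per_frame,
                               margin_um=margin_um,
                               rng=np.random.default_rng(s_pos))
    stack = render_stack(truth, optical, emitter,
                         seed=int(s_render.generate_state(1)[0] % (2 ** 31)))
    return stack, truth


def detect_once(stack: ImageStack, analysis: AnalysisConfig | None = None,
                d_hint_um2_s: float | None = None,
                **kwargs) -> tuple[pd.DataFrame, float]:
    """Detect spots and return them with the per-stack sigma_loc estimate.

    ``d_hint_um2_s`` (e.g. the FCS diffusion constant, or the true value in
    a simulation study) sets blur-matched detection parameters; explicit
    keyword arguments override them.  ``sigma_loc`` comes from the
    photon-count route (median over spots) unless the analysis config pins
    a value.
    """
    analysis = analysis or AnalysisConfig()
    kwargs.setdefault("threshold_k", analysis.threshold_k)
    if d_hint_um2_s is not None:
        for key, val in detect_params_for(stack.optical, d_hint_um2_s).items():
            kwargs.setdefault(key, val)
    spots = detect_spots(stack, **kwargs)
    if analysis.sigma_loc_um is not None:
        return spots, float(analysis.sigma_loc_um)
    if len(spots) == 0:
        return spots, 0.0
    sig = estimate_localization_sigma(spots=spots)
    return spots, sig.sigma_um


@dataclass
class CellResult:
    mlr_um: float
    centroid_log10: float
    d_centroid_um2_s: float
    n_tracks: int
    n_excluded_nonpositive: int
    valid: bool


def centroid_at_mlrs(spots: pd.DataFrame, mlrs, timing: TimingInfo,
                     sigma_loc_um: float, method: str = "ss",
                     min_tracks: int = 30) -> list[CellResult]:
    """Link one spot table at several MLRs and fit the logD_c centroid."""
    out = []
    for mlr in mlrs:
        ts = link_spots(spots, LinkConfig(mlr_um=float(mlr)))
        est = estimates_table(ts, timing, sigma_loc_um, method=method)
        n = len(est)
        if n == 0 or (est["D_um2_s"] > 0).sum() < 5:
            out.append(CellResult(float(mlr), float("nan"), float("nan"),
                                  n, 0, False))
            continue
        fit = fit_lognormal_centroid(est, min_positive=min_tracks)
        out.append(CellResult(float(mlr), fit.centroid_log10,
                              fit.centroid_um2_s, n,
                              fit.n_excluded_nonpositive,
                              n >= max(5, min_tracks // 3)))
    return out
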