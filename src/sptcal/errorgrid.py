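"""Diffusion-accuracy study: relative error versus D, density and MLR.

Reproduces the simulation protocol of the accuracy figure: ideal Brownian
motion without photobleaching over a grid of true diffusion constants
(1, 5, 11 um^2 s^-1) and surface densities (0.001-0.125 um^-2), tracked at
several MLRs (1.0, 2.3, 8.4, 15.1 um), with the blur/localization-corrected
single-step estimator and a log-normal centroid fit, repeated over seeds to
give a mean and standard deviation per condition.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import EmitterModel, OpticalTimingConfig, SampleConfig, TimingInfo
from .pipeline import centroid_at_mlrs, detect_once, simulate_stack

__all__ = ["GridConfig", "ErrorGrid", "run_grid", "relative_error"]

DEFAULT_DENSITIES = tuple(np.geomspace(0.001, 0.125, 6).round(6))


def relative_error(d_est: float, d_true: float) -> float:
    """Percent relative error 100 * (D_est - D_true) / D_true."""
    if d_true <= 0:
        raise ValueError("D_true must be positive")
    return 100.0 * (d_est - d_true) / d_true


@dataclass(frozen=True)
class GridConfig:
    d_values: tuple[float, ...] = (1.0, 5.0, 11.0)
    densities: tuple[float, ...] = DEFAULT_DENSITIES
    mlrs: tuple[float, ...] = (1.0, 2.3, 8.4, 15.1)
    n_frames: int = 800
    n_replicates: int = 3
    optical: OpticalTimingConfig = field(default_factory=OpticalTimingConfig)
    emitter: EmitterModel = field(default_factory=lambda: EmitterModel(
        bleach_mean_photons=math.inf))   # no photobleaching in the grid
    min_tracks: int = 30
    method: str = "ss"

    def __post_init__(self) -> None:
        if not math.isinf(self.emitter.bleach_mean_photons):
            raise ValueError("the accuracy grid models ideal Brownian motion "
                             "without photobleaching")


@dataclass
class ErrorGrid:
    df: pd.DataFrame      # d_true, density, mlr, replicate, error_pct, ...
    config: GridConfig

    def cell_means(self) -> pd.DataFrame:
        """Per-(D, density, MLR) mean and SD of the relative error."""
        g = self.df[self.df["valid"]].groupby(["d_true", "density", "mlr"])
        out = g["error_pct"].agg(["mean", "std", "count"]).reset_index()
        return out.rename(columns={"mean": "error_mean_pct",
                                   "std": "error_sd_pct",
                                   "count": "n_replicates"})


def run_grid(config: GridConfig, seed: int = 0,
             progress: bool = False) -> ErrorGrid:
    """Run the full accuracy grid.

    One stack is simulated per (D, density, replicate); detection runs
    once per stack and the linker is re-run at every MLR.  Cells whose
    trajectory count is too small are marked invalid rather than
    zero-filled.
    """
    optical = dataclasses.replace(config.optical, n_frames=config.n_frames)
    timing = TimingInfo.from_optical(optical)
    ss = np.random.SeedSequence(seed)
    rows = []
    n_cells = len(config.d_values) * len(config.densities) * config.n_replicates
    child = iter(ss.spawn(n_cells))
    for d_true in config.d_values:
        for density in config.densities:
            for rep in range(config.n_replicates):
                cell_seed = int(next(child).generate_state(1)[0] % (2 ** 31))
                sample = SampleConfig(diffusion_um2_s=d_true,
                                      density_um2=density, seed=cell_seed)
                stack, _ = simulate_stack(sample, optical, config.emitter,
                                          seed=cell_seed)
                spots, sigma_loc = detect_once(stack, d_hint_um2_s=d_true)
                results = centroid_at_mlrs(spots, config.mlrs, timing,
                                           sigma_loc, method=config.method,
                                           min_tracks=config.min_tracks)
                for res in results:
                    err = (relative_error(res.d_centroid_um2_s, d_true)
                           if np.isfinite(res.d_centroid_um2_s) else np.nan)
                    rows.append({
                        "d_true": d_true, "density": density,
                        "mlr": res.mlr_um, "replicate": rep,
                        "seed": cell_seed, "centroid_log10": res.centroid_log10,
                        "d_est": res.d_centroid_um2_s, "error_pct": err,
                        "n_tracks": res.n_tracks, "valid": res.valid,
                        "sigma_loc_um": sigma_loc,
                    })
                if progress:   # pragma: no cover - cosmetic
                    print(f"D={d_true} density={density} rep={rep} done",
                          flush=True)
    return ErrorGrid(df=pd.DataFrame(rows), config=config)


def plot_grid(grid: ErrorGrid, path=None):   # pragma: no cover - optional plot
    """Error-versus-density panels, one per true D, lines per MLR."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cm = grid.cell_means()
    d_values = sorted(cm["d_true"].unique())
    fig, axes = plt.subplots(1, len(d_values), figsize=(4 * len(d_values), 3.2),
                             sharey=False)
    axes = np.atleast_1d(axes)
    for ax, d in zip(axes, d_values):
        sub = cm[cm["d_true"] == d]
        for mlr, g in sub.groupby("mlr"):
            g = g.sort_values("density")
            ax.errorbar(g["density"], g["error_mean_pct"],
                        yerr=g["error_sd_pct"], marker="o",
                        label=f"MLR {mlr} um")
        ax.set_xscale("log")
        ax.set_xlabel("density (um$^{-2}$)")
        ax.set_title(f"D = {d} um$^2$/s")
    axes[0].set_ylabel("diffusion error (%)")
    axes[-1].legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
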