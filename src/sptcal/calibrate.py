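"""Selecting the optimal maximum linking radius (MLR).

Two complementary diagnostics are implemented:

* **FCS crossing** - sweep the linker over candidate MLRs, fit the
  per-trajectory diffusion-constant distribution at each radius, and find
  the MLR where the centroid curve logD_c(MLR) equals the FCS-measured
  diffusion constant.  The sweep is monotone-regularized (isotonic fit)
  before interpolation because stochastic sweeps can be locally
  non-monotone.

* **Squared-displacement kink** - histogram the consecutive-frame squared
  displacements obtained at a generous MLR on a semilogarithmic scale; for
  correctly linked homogeneous Brownian motion ln(counts) is linear in SD,
  and false links add a flatter tail.  A continuous two-segment linear fit
  locates the breakpoint; its square root is the optimal MLR (the SD-axis
  convention; a displacement-axis variant is also available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import isotonic_regression

from .config import LinkConfig, TimingInfo
from .diffusion import estimates_table, fit_lognormal_centroid
from .tracking import TrackSet, link_spots

__all__ = ["mlr_sweep", "sweep_replicates", "optimal_mlr_from_fcs",
           "sd_histogram", "kink_mlr", "calibrate", "SweepResult",
           "SDHistogram", "KinkResult", "CalibrationResult"]


# ---------------------------------------------------------------------------
# centroid-versus-MLR sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    mlr_grid: np.ndarray
    centroid_log10: np.ndarray
    n_tracks: np.ndarray
    flagged: np.ndarray          # too few trajectories at this MLR
    method: str
    tracksets: dict = field(default_factory=dict)   # mlr -> TrackSet (optional)


def mlr_sweep(spots: pd.DataFrame, mlr_grid, timing: TimingInfo,
              sigma_loc_um: float = 0.0, method: str = "ss",
              min_tracks: int = 30, keep_tracks: tuple[float, ...] = (),
              ap_max_lag: int = 10) -> SweepResult:
    """Link one spot table at every candidate MLR and fit logD_c.

    Detection is done once upstream; only the linking step is repeated.
    Grid points yielding fewer than ``min_tracks`` trajectories are
    flagged, not fatal.  TrackSets for MLRs listed in ``keep_tracks`` are
    retained on the result (for the kink diagnostic).
    """
    grid = np.asarray(sorted(mlr_grid), dtype=float)
    if len(grid) < 2:
        raise ValueError("need at least 2 grid points")
    cents, ns, flags = [], [], []
    kept: dict[float, TrackSet] = {}
    for mlr in grid:
        ts = link_spots(spots, LinkConfig(mlr_um=float(mlr)))
        est = estimates_table(ts, timing, sigma_loc_um, method=method,
                              ap_max_lag=ap_max_lag)
        n = len(est)
        if n == 0 or (est["D_um2_s"] > 0).sum() == 0:
            cents.append(np.nan)
            ns.append(n)
            flags.append(True)
            continue
        fit = fit_lognormal_centroid(est, min_positive=min_tracks)
        cents.append(fit.centroid_log10)
        ns.append(n)
        flags.append(n < min_tracks)
        if any(abs(mlr - k) < 1e-9 for k in keep_tracks):
            kept[float(mlr)] = ts
    return SweepResult(mlr_grid=grid, centroid_log10=np.array(cents),
                       n_tracks=np.array(ns), flagged=np.array(flags),
                       method=method, tracksets=kept)


def sweep_replicates(spot_sets, mlr_grid, timing: TimingInfo,
                     sigma_locs=None, method: str = "ss",
                     min_tracks: int = 30,
                     keep_tracks: tuple[float, ...] = ()):
    """Run :func:`mlr_sweep` over replicate spot tables.

    Returns ``(mean_curve, sd_curve, sweeps)`` where the curves are over
    the shared grid and ``sweeps`` is the per-replicate list.
    """
    if sigma_locs is None:
        sigma_locs = [0.0] * len(spot_sets)
    sweeps = [mlr_sweep(s, mlr_grid, timing, sig, method=method,
                        min_tracks=min_tracks, keep_tracks=keep_tracks)
              for s, sig in zip(spot_sets, sigma_locs)]
    mat = np.stack([s.centroid_log10 for s in sweeps])
    return np.nanmean(mat, axis=0), np.nanstd(mat, axis=0), sweeps


def optimal_mlr_from_fcs(mlr_grid, centroid_log10, d_fcs_um2_s: float,
                         tol: float = 0.05) -> float:
    """MLR where the (isotonic-regularized) sweep crosses log10(D_fcs).

    Returns NaN with a warning when the sweep does not bracket the FCS
    value; extend the grid in that case.
    """
    grid = np.asarray(mlr_grid, dtype=float)
    y = np.asarray(centroid_log10, dtype=float)
    ok = np.isfinite(y)
    grid, y = grid[ok], y[ok]
    if len(grid) < 2:
        warnings.warn("too few valid sweep points", stacklevel=2)
        return float("nan")
    iso = isotonic_regression(y).x
    if np.max(np.abs(y - iso)) > tol:
        warnings.warn("sweep is non-monotone beyond tolerance; "
                      "isotonic fit applied", stacklevel=2)
    target = np.log10(d_fcs_um2_s)
    if target < iso[0] or target > iso[-1]:
        warnings.warn(
            f"sweep does not bracket log10(D_fcs) = {target:.3f}; extend the "
            "MLR grid", stacklevel=2)
        return float("nan")
    i = int(np.searchsorted(iso, target, side="left"))
    if i == 0:
        return float(grid[0])
    x0, x1, y0, y1 = grid[i - 1], grid[i], iso[i - 1], iso[i]
    if y1 == y0:
        return float(x0)
    return float(x0 + (target - y0) / (y1 - y0) * (x1 - x0))


def plateau_onset(mlr_grid, centroid_log10, tol: float = 0.05) -> float:
    """Smallest MLR whose centroid is within ``tol`` decades of the plateau
    (the sweep maximum) - the failure mode of plateau-based calibration."""
    grid = np.asarray(mlr_grid, dtype=float)
    y = np.asarray(centroid_log10, dtype=float)
    ok = np.isfinite(y)
    grid, y = grid[ok], y[ok]
    top = np.nanmax(y)
    idx = np.flatnonzero(y >= top - tol)
    return float(grid[idx[0]]) if len(idx) else float("nan")


# ---------------------------------------------------------------------------
# squared-displacement histogram and kink
# ---------------------------------------------------------------------------

@dataclass
class SDHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    axis: str = "sd"        # "sd" (um^2) or "displacement" (um)
    n_steps: int = 0

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def log_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(centers, ln counts) over nonempty bins."""
        m = self.counts > 0
        return self.centers[m], np.log(self.counts[m])


def sd_histogram(tracks: TrackSet | pd.DataFrame, bin_width: float = 0.25,
                 axis: str = "sd", min_steps: int = 500) -> SDHistogram:
    """Histogram of consecutive-frame squared displacements.

    Link at a generous MLR (the sweep maximum) before calling this so the
    false-link tail is present in the data.
    """
    if axis not in ("sd", "displacement"):
        raise ValueError("axis must be 'sd' or 'displacement'")
    steps = tracks.steps() if isinstance(tracks, TrackSet) else tracks
    sd = steps["sd_um2"].to_numpy(dtype=float)
    if len(sd) < min_steps:
        raise ValueError(f"need >= {min_steps} steps, got {len(sd)}")
    x = sd if axis == "sd" else np.sqrt(sd)
    hi = x.max() + bin_width
    edges = np.arange(0.0, hi + bin_width, bin_width)
    counts, edges = np.histogram(x, bins=edges)
    return SDHistogram(bin_edges=edges, counts=counts, axis=axis,
                       n_steps=len(sd))


@dataclass
class KinkResult:
    mlr_um: float               # NaN when no kink is detected
    breakpoint: float           # on the histogram axis
    slopes: tuple[float, float]
    f_pvalue: float
    has_kink: bool
    axis: str
    sse_two_segment: float = float("nan")


def kink_mlr(hist: SDHistogram, min_seg_bins: int = 3,
             alpha: float = 0.01) -> KinkResult:
    """Continuous two-segment linear fit of ln(counts) versus SD.

    The breakpoint is found by grid search over interior bin centres
    (weighted least squares, weights sqrt(count) since the variance of
    ln n is ~1/n for Poisson counts).  An F-test against a single line
    guards the degenerate case: when a single slope is not rejected at
    ``alpha`` the no-kink flag is set and the MLR is NaN.
    """
    x, y = hist.log_counts()
    n = len(x)
    if n < 2 * min_seg_bins + 2:
        raise ValueError("histogram has too few populated bins")
    w = np.sqrt(hist.counts[hist.counts > 0].astype(float))

    def wfit(X):
        Xw = X * w[:, None]
        yw = y * w
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        sse = float(((yw - Xw @ beta) ** 2).sum())
        return beta, sse

    one = np.stack([np.ones(n), x], axis=1)
    beta1, sse1 = wfit(one)

    best = (None, np.inf, None)
    for i in range(min_seg_bins, n - min_seg_bins):
        bp = x[i]
        X = np.stack([np.ones(n), x, np.clip(x - bp, 0.0, None)], axis=1)
        beta, sse = wfit(X)
        if sse < best[1]:
            best = (bp, sse, beta)
    bp, sse2, beta = best
    dof = n - 4   # intercept, slope, slope change, breakpoint
    f = max(sse1 - sse2, 0.0) / 2.0 / (sse2 / max(dof, 1))
    pval = float(stats.f.sf(f, 2, max(dof, 1)))
    has_kink = pval < alpha
    slopes = (float(beta[1]), float(beta[1] + beta[2]))
    if not has_kink:
        return KinkResult(float("nan"), float("nan"), slopes, pval, False,
                          hist.axis, sse2)
    mlr = float(np.sqrt(bp)) if hist.axis == "sd" else float(bp)
    return KinkResult(mlr, float(bp), slopes, pval, True, hist.axis, sse2)


# ---------------------------------------------------------------------------
# full calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    mlr_grid: np.ndarray
    centroid_log10: np.ndarray       # mean over replicates
    centroid_sd: np.ndarray
    d_fcs_um2_s: float
    crossing_mlr_um: float
    kink_mlr_um: float
    plateau_onset_mlr_um: float
    kink: KinkResult | None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mlr_grid_um": list(map(float, self.mlr_grid)),
            "centroid_log10": [None if not np.isfinite(v) else float(v)
                               for v in self.centroid_log10],
            "centroid_sd": list(map(float, self.centroid_sd)),
            "d_fcs_um2_s": float(self.d_fcs_um2_s),
            "crossing_mlr_um": float(self.crossing_mlr_um),
            "kink_mlr_um": float(self.kink_mlr_um),
            "plateau_onset_mlr_um": float(self.plateau_onset_mlr_um),
            "metadata": self.metadata,
        }


def calibrate(spot_sets, mlr_grid, d_fcs_um2_s: float, timing: TimingInfo,
              sigma_locs=None, method: str = "ss",
              kink_axis: str = "sd", bin_width: float = 0.25,
              min_tracks: int = 30) -> CalibrationResult:
    """End-to-end MLR calibration over replicate spot tables.

    Runs the sweep per replicate, crosses the replicate-mean curve with
    the FCS diffusion constant, and locates the kink on the pooled lag-1
    SD histogram linked at the sweep maximum.
    """
    grid = np.asarray(sorted(mlr_grid), dtype=float)
    top = float(grid[-1])
    mean_c, sd_c, sweeps = sweep_replicates(
        spot_sets, grid, timing, sigma_locs, method=method,
        min_tracks=min_tracks, keep_tracks=(top,))
    crossing = optimal_mlr_from_fcs(grid, mean_c, d_fcs_um2_s)
    steps = pd.concat([s.tracksets[top].steps() for s in sweeps],
                      ignore_index=True)
    hist = sd_histogram(steps, bin_width=bin_width, axis=kink_axis)
    kink = kink_mlr(hist)
    onset = plateau_onset(grid, mean_c)
    meta = {"method": method, "kink_axis": kink_axis,
            "n_replicates": len(spot_sets),
            "n_tracks": [list(map(int, s.n_tracks)) for s in sweeps]}
    return CalibrationResult(
        mlr_grid=grid, centroid_log10=mean_c, centroid_sd=sd_c,
        d_fcs_um2_s=d_fcs_um2_s, crossing_mlr_um=crossing,
        kink_mlr_um=kink.mlr_um, plateau_onset_mlr_um=onset, kink=kink,
        metadata=meta)
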