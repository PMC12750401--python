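"""Squared displacements, MSD and blur-corrected diffusion estimators.

Estimates follow the standard static + dynamic error model for a camera
with exposure ``dT_exp`` inside a frame interval ``dt``:

    MSD_obs(n) = 4 D (n dt - dT_exp / 3) + 4 sigma_loc^2

so the single-step (SS) estimator is
``D = (<SD, lag 1> - 4 sigma_loc^2) / (4 (dt - dT_exp/3))`` and the
all-pairs (AP) estimator averages the per-lag inversions without
regression.  Negative corrected values are retained in the per-trajectory
record and excluded (with a count) from the logarithmic-Gaussian centroid
fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .config import TimingInfo
from .tracking import TrackSet

__all__ = ["squared_displacements", "msd_curve", "d_single_step",
           "d_all_pairs", "estimates_table", "fit_lognormal_centroid",
           "DistributionFit"]


def _as_xy(traj) -> np.ndarray:
    if isinstance(traj, pd.DataFrame):
        return traj[["x_um", "y_um"]].to_numpy(dtype=float)
    a = np.asarray(traj, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2:
        raise ValueError("trajectory must be an (n, 2) array of positions")
    return a


def squared_displacements(traj, lag_frames: int = 1) -> np.ndarray:
    """All squared displacements at a given lag along one trajectory."""
    if lag_frames < 1:
        raise ValueError("lag must be >= 1")
    xy = _as_xy(traj)
    if len(xy) < lag_frames + 1:
        raise ValueError("trajectory too short for this lag")
    d = xy[lag_frames:] - xy[:-lag_frames]
    return (d ** 2).sum(axis=1)


def msd_curve(traj, max_lag: int | None = None,
              max_lag_frac: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged MSD over lags 1..max_lag; returns (lags, msd)."""
    xy = _as_xy(traj)
    if len(xy) < 2:
        raise ValueError("trajectory needs at least 2 points")
    top = max(1, int(math.floor((len(xy) - 1) * max_lag_frac)))
    if max_lag is not None:
        top = min(top, max_lag)
    top = max(top, 1)
    lags = np.arange(1, top + 1)
    msd = np.array([squared_displacements(xy, int(k)).mean() for k in lags])
    return lags, msd


def _blur_denominator(lag: float, timing: TimingInfo) -> float:
    return 4.0 * (lag * timing.frame_interval_s - timing.exposure_s / 3.0)


def d_single_step(traj, timing: TimingInfo, sigma_loc_um: float = 0.0) -> float:
    """Blur/localization-corrected single-step (SS) diffusion estimate."""
    if sigma_loc_um < 0:
        raise ValueError("sigma_loc must be >= 0")
    mean_sd = squared_displacements(traj, 1).mean()
    return (mean_sd - 4.0 * sigma_loc_um ** 2) / _blur_denominator(1, timing)


def d_all_pairs(traj, timing: TimingInfo, sigma_loc_um: float = 0.0,
                max_lag: int = 10) -> float:
    """All-pairs (AP) nonregression estimate: unweighted mean over per-lag
    corrected diffusion constants up to ``min(max_lag, ceil(points/2))``."""
    xy = _as_xy(traj)
    if len(xy) < 2:
        raise ValueError("trajectory needs at least 2 points")
    top = min(max_lag, max(1, math.ceil(len(xy) / 2)))
    lags, msd = msd_curve(xy, max_lag=top, max_lag_frac=1.0)
    d_n = (msd - 4.0 * sigma_loc_um ** 2) / \
        np.array([_blur_denominator(int(k), timing) for k in lags])
    return float(d_n.mean())


def estimates_table(tracks: TrackSet, timing: TimingInfo,
                    sigma_loc_um: float = 0.0, method: str = "ss",
                    ap_max_lag: int = 10) -> pd.DataFrame:
    """Per-trajectory diffusion estimates for every track in a TrackSet."""
    if method not in ("ss", "ap"):
        raise ValueError("method must be 'ss' or 'ap'")
    rows = []
    for tid, xy in tracks.track_arrays():
        if len(xy) < 2:
            continue
        if method == "ss":
            d = d_single_step(xy, timing, sigma_loc_um)
        else:
            d = d_all_pairs(xy, timing, sigma_loc_um, max_lag=ap_max_lag)
        rows.append((tid, method, d, len(xy) - 1))
    return pd.DataFrame(rows, columns=["track_id", "method", "D_um2_s",
                                       "n_steps"])


# ---------------------------------------------------------------------------
# logarithmic-Gaussian centroid fit
# ---------------------------------------------------------------------------

@dataclass
class DistributionFit:
    """Log10-Gaussian fit of a per-trajectory diffusion distribution."""

    centroid_log10: float
    width_log10: float
    amplitude: float
    bin_edges: np.ndarray
    counts: np.ndarray
    residual: float
    n_used: int
    n_excluded_nonpositive: int
    method: str = "gauss-fit"   # or "median-fallback"
    extra: dict = field(default_factory=dict)

    @property
    def centroid_um2_s(self) -> float:
        return 10.0 ** self.centroid_log10


def _gauss(x, a, mu, s):
    return a * np.exp(-0.5 * ((x - mu) / s) ** 2)


def fit_lognormal_centroid(estimates, bin_width: float = 0.1,
                           min_positive: int = 30,
                           bin_origin: float = 0.0) -> DistributionFit:
    """Histogram log10 of the positive estimates and fit a Gaussian.

    The centroid is the fitted mean of the log10(D) histogram (the logD_c
    summary statistic).  Nonpositive estimates cannot enter log space;
    they are excluded and counted.  If the sample is smaller than ``min_positive``
    or the least-squares fit fails, the median of log10(D) is reported as
    a flagged fallback.
    """
    if isinstance(estimates, pd.DataFrame):
        d = estimates["D_um2_s"].to_numpy(dtype=float)
    else:
        d = np.asarray(estimates, dtype=float)
    d = d[np.isfinite(d)]
    pos = d[d > 0]
    n_excl = int(len(d) - len(pos))
    if len(pos) == 0:
        raise ValueError("no positive diffusion estimates to fit")
    logd = np.log10(pos)

    lo = bin_origin + math.floor((logd.min() - bin_origin) / bin_width) * bin_width
    hi = bin_origin + math.ceil((logd.max() - bin_origin) / bin_width + 1e-9) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 2:
        edges = np.array([lo - bin_width / 2, lo + bin_width / 2])
    counts, edges = np.histogram(logd, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    fallback = DistributionFit(
        centroid_log10=float(np.median(logd)), width_log10=float(np.std(logd)),
        amplitude=float(counts.max()) if len(counts) else 0.0,
        bin_edges=edges, counts=counts, residual=float("nan"),
        n_used=len(pos), n_excluded_nonpositive=n_excl,
        method="median-fallback")
    if len(pos) < min_positive or (counts > 0).sum() < 4:
        return fallback

    # Initialise at the histogram mode and iteratively restrict the fit to
    # bins near the current centre: linking errors contaminate the
    # distribution with a heavy tail, and the centroid of interest is the
    # central peak, not a tail-inflated mean.
    mu0 = float(centers[np.argmax(counts)])
    s0 = max(float(np.std(logd)), bin_width)
    popt = (float(counts.max()), mu0, s0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(3):
                a0, m0, w0 = popt
                window = np.abs(centers - m0) <= 2.5 * max(abs(w0), bin_width)
                if window.sum() < 5:
                    window = np.ones_like(centers, dtype=bool)
                popt, _ = curve_fit(_gauss, centers[window], counts[window],
                                    p0=popt, maxfev=5000)
    except RuntimeError:
        return fallback
    a, mu, s = popt
    if not np.isfinite(mu) or abs(mu - np.mean(logd)) > 5 * (np.std(logd) + bin_width):
        return fallback
    resid = float(np.sqrt(np.mean((counts - _gauss(centers, *popt)) ** 2)))
    return DistributionFit(centroid_log10=float(mu), width_log10=abs(float(s)),
                           amplitude=float(a), bin_edges=edges, counts=counts,
                           residual=resid, n_used=len(pos),
                           n_excluded_nonpositive=n_excl)
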