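"""Fluorescence correlation spectroscopy: correlator and 2D diffusion fit.

The normalized autocorrelation ``G(tau) = <dF(t) dF(t+tau)> / <F>^2`` of a
binned photon trace is computed with the multiple-tau scheme (m lags per
octave, successive binning by 2), the software equivalent of a hardware
correlator.  The two-dimensional free-diffusion model

    G2D(tau) = (1/<N>) * (1 + tau/tau_D)^-1

is fitted by (optionally weighted) least squares; the diffusion constant
follows from the 1/e^2 detection radius as ``D = omega_1^2 / (4 tau_D)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .simulate import PhotonTrace

__all__ = ["AutocorrelationCurve", "FcsFit", "autocorrelate",
           "fit_g2d", "fit_g2d_joint", "d_from_tau"]


@dataclass
class AutocorrelationCurve:
    lag_s: np.ndarray
    g: np.ndarray
    stderr: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lag_s) <= 0) or np.any(self.lag_s <= 0):
            raise ValueError("lags must be strictly increasing and positive")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("G values must be finite")


@dataclass
class FcsFit:
    n_mean: float
    tau_D_s: float
    g0: float
    omega1_nm: float | None = None
    D_um2_s: float | None = None
    ci95: dict = field(default_factory=dict)
    covariance: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_mean <= 0 or self.tau_D_s <= 0:
            raise ValueError("N and tau_D must be positive")


def _corr_at_lag(f: np.ndarray, k: int) -> float:
    """Symmetric-normalized correlation of one array at integer lag k."""
    a, b = f[:-k], f[k:]
    ma, mb = a.mean(), b.mean()
    if ma == 0.0 or mb == 0.0:
        return 0.0
    return float((a * b).mean() / (ma * mb) - 1.0)


def autocorrelate(trace: PhotonTrace, m_per_octave: int = 16) -> AutocorrelationCurve:
    """Multiple-tau autocorrelation of a photon trace.

    Level 0 evaluates lags ``1..2m`` on the raw bins; each further level
    halves the time resolution by pairwise binning and evaluates lags
    ``m+1..2m`` in the coarser units, giving pseudo-logarithmic spacing.
    Normalization is symmetric (left/right segment means), so
    ``G(tau -> 0) -> 1/<N>`` for the 2D model.
    """
    f = np.asarray(trace.counts, dtype=float)
    if len(f) < 2 ** 10:
        raise ValueError("trace must contain at least 2^10 bins")
    if f.mean() == 0.0:
        raise ValueError("trace mean is zero; cannot normalize")
    m = int(m_per_octave)
    dwell = trace.dwell_s
    lags: list[float] = []
    g: list[float] = []
    for k in range(1, 2 * m + 1):
        if k >= len(f):
            break
        lags.append(k * dwell)
        g.append(_corr_at_lag(f, k))
    level = 1
    fl = f
    while True:
        n2 = len(fl) // 2
        if n2 < 2 * m + 1:
            break
        fl = fl[:2 * n2].reshape(n2, 2).mean(axis=1)
        width = dwell * 2 ** level
        for k in range(m + 1, 2 * m + 1):
            if k >= len(fl):
                break
            lags.append(k * width)
            g.append(_corr_at_lag(fl, k))
        level += 1
    return AutocorrelationCurve(lag_s=np.array(lags), g=np.array(g),
                                meta={"dwell_s": dwell, "m": m,
                                      "mean_rate_hz": f.mean() / dwell})


def _model(tau, g0, tau_d):
    return g0 / (1.0 + tau / tau_d)


def _default_window(curve: AutocorrelationCurve,
                    min_lag_bins: int = 5) -> np.ndarray:
    dwell = curve.meta.get("dwell_s", curve.lag_s[0])
    return curve.lag_s >= min_lag_bins * dwell


def _p0(tau: np.ndarray, g: np.ndarray) -> tuple[float, float]:
    g0 = max(float(g[0]), 1e-12)
    below = np.flatnonzero(g <= g0 / 2.0)
    tau_d0 = float(tau[below[0]]) if len(below) else float(tau[-1])
    return g0, max(tau_d0, float(tau[0]))


def fit_g2d(curve: AutocorrelationCurve, lag_window: tuple[float, float] | None = None,
            omega1_nm: float | None = None, min_lag_bins: int = 5,
            weights: np.ndarray | None = None) -> FcsFit:
    """Fit the 2D diffusion model to an autocorrelation curve.

    ``lag_window`` restricts the fit to ``lo <= tau <= hi`` seconds; by
    default lags below ``min_lag_bins`` dwell times are excluded
    (afterpulsing / shot-noise regime).  Weights (1/sigma) are used when
    the curve carries uncertainties or they are passed explicitly.
    """
    mask = _default_window(curve, min_lag_bins)
    if lag_window is not None:
        lo, hi = lag_window
        mask &= (curve.lag_s >= lo) & (curve.lag_s <= hi)
    tau, g = curve.lag_s[mask], curve.g[mask]
    if len(tau) < 8:
        raise ValueError("need at least 8 lags in the fit window")
    sigma = None
    if weights is not None:
        sigma = 1.0 / np.asarray(weights)[mask]
    elif curve.stderr is not None:
        sigma = np.clip(curve.stderr[mask], 1e-12, None)
    popt, pcov = curve_fit(_model, tau, g, p0=_p0(tau, g), sigma=sigma,
                           absolute_sigma=False, maxfev=10000)
    g0, tau_d = float(popt[0]), float(popt[1])
    if g0 <= 0 or tau_d <= 0:
        raise RuntimeError(f"non-physical fit: G0={g0:.3g}, tau_D={tau_d:.3g}")
    err = 1.96 * np.sqrt(np.clip(np.diag(pcov), 0, None))
    ci = {"g0": float(err[0]), "tau_D_s": float(err[1])}
    d = None
    if omega1_nm is not None:
        d = d_from_tau(tau_d, omega1_nm)
        ci["D_um2_s"] = d * ci["tau_D_s"] / tau_d
    return FcsFit(n_mean=1.0 / g0, tau_D_s=tau_d, g0=g0, omega1_nm=omega1_nm,
                  D_um2_s=d, ci95=ci, covariance=pcov)


def fit_g2d_joint(curves: list[AutocorrelationCurve],
                  omega1_nm: float | None = None,
                  min_lag_bins: int = 5) -> FcsFit:
    """Simultaneous fit of several curves with a shared tau_D.

    Each curve keeps its own amplitude (occupancy differs between
    positions/powers); the crossing time is common.  Mirrors fitting
    replicate measurements collectively.
    """
    data = []
    for c in curves:
        mask = _default_window(c, min_lag_bins)
        data.append((c.lag_s[mask], c.g[mask]))
    g0s = [_p0(t, g)[0] for t, g in data]
    tau0 = float(np.median([_p0(t, g)[1] for t, g in data]))

    def resid(p):
        tau_d = p[0]
        return np.concatenate([
            _model(t, p[1 + i], tau_d) - g for i, (t, g) in enumerate(data)])

    res = least_squares(resid, x0=[tau0] + g0s,
                        bounds=([1e-9] + [1e-12] * len(g0s), np.inf))
    tau_d = float(res.x[0])
    g0 = float(np.mean(res.x[1:]))
    # covariance from the Jacobian at the solution
    ci = {}
    try:
        J = res.jac
        dof = max(len(res.fun) - len(res.x), 1)
        cov = np.linalg.inv(J.T @ J) * 2 * res.cost / dof
        ci["tau_D_s"] = 1.96 * float(np.sqrt(cov[0, 0]))
    except np.linalg.LinAlgError:   # pragma: no cover
        cov = None
    d = d_from_tau(tau_d, omega1_nm) if omega1_nm is not None else None
    return FcsFit(n_mean=1.0 / g0, tau_D_s=tau_d, g0=g0, omega1_nm=omega1_nm,
                  D_um2_s=d, ci95=ci, covariance=cov)


def d_from_tau(tau_D_s: float, omega1_nm: float) -> float:
    """Diffusion constant from the crossing time: D = omega_1^2 / (4 tau_D)."""
    if tau_D_s <= 0 or omega1_nm <= 0:
        raise ValueError("tau_D and omega_1 must be positive")
    omega_um = omega1_nm / 1000.0
    return omega_um ** 2 / (4.0 * tau_D_s)
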