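"""Spot detection and cost-matrix trajectory linking.

Detection: difference-of-Gaussians bandpass matched to the PSF (plus motion
blur), robust median + k*MAD thresholding, local-maximum candidates and
sub-pixel refinement by a least-squares fit of a pixel-integrated 2D
Gaussian (vectorised Gauss-Newton over all spots at once; intensity-weighted
centroid available as fallback).

Linking: per consecutive frame pair the linear assignment problem with
squared displacement as cost, candidate links beyond the maximum linking
radius (MLR) forbidden, and birth/death costs of MLR^2 (the standard LAP
convention).  The time-based link range is one frame: no gap closing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.special import erf

from .config import LinkConfig, OpticalTimingConfig
from .simulate import ImageStack

__all__ = ["detect_spots", "link_spots", "TrackSet",
           "estimate_localization_sigma", "apparent_density",
           "LocalizationSigma"]

_BIG = 1e9

SPOT_COLUMNS = ["frame", "x_um", "y_um", "intensity", "width_px",
                "sigma_loc_um", "background"]


# ---------------------------------------------------------------------------
# sub-pixel refinement
# ---------------------------------------------------------------------------

def _fit_gaussian_spots(windows: np.ndarray, sigma0: float,
                        n_iter: int = 15,
                        fit_sigma: bool = True) -> np.ndarray:
    """Batched Gauss-Newton fit of a pixel-integrated Gaussian.

    ``windows``: (n, w, w) pixel counts.  Returns (n, 5) parameters
    ``x0, y0, A, b, sigma`` with positions in pixel units relative to the
    window centre pixel's centre.
    """
    n, w, _ = windows.shape
    r = w // 2
    c = np.arange(w, dtype=float) - r          # pixel-centre offsets
    cx = np.broadcast_to(c[None, :], (w, w)).ravel()
    cy = np.broadcast_to(c[:, None], (w, w)).ravel()
    data = windows.reshape(n, -1).astype(float)

    # initial values from an intensity-weighted centroid
    edge = np.concatenate([windows[:, 0, :], windows[:, -1, :],
                           windows[:, :, 0], windows[:, :, -1]], axis=1)
    b = np.median(edge, axis=1)
    resid = np.clip(data - b[:, None], 0.0, None)
    tot = resid.sum(axis=1)
    tot_safe = np.where(tot > 0, tot, 1.0)
    x0 = (resid * cx).sum(axis=1) / tot_safe
    y0 = (resid * cy).sum(axis=1) / tot_safe
    A = np.clip(tot, 1.0, None)
    sig = np.full(n, float(sigma0))

    lam = 1e-2
    for _ in range(n_iter):
        s = sig[:, None]
        up_x, lo_x = (cx[None] - x0[:, None] + 0.5), (cx[None] - x0[:, None] - 0.5)
        up_y, lo_y = (cy[None] - y0[:, None] + 0.5), (cy[None] - y0[:, None] - 0.5)
        sq2 = np.sqrt(2.0)
        Ex = 0.5 * (erf(up_x / (sq2 * s)) - erf(lo_x / (sq2 * s)))
        Ey = 0.5 * (erf(up_y / (sq2 * s)) - erf(lo_y / (sq2 * s)))
        norm = 1.0 / (np.sqrt(2 * np.pi) * s)
        phi_ux = norm * np.exp(-up_x ** 2 / (2 * s ** 2))
        phi_lx = norm * np.exp(-lo_x ** 2 / (2 * s ** 2))
        phi_uy = norm * np.exp(-up_y ** 2 / (2 * s ** 2))
        phi_ly = norm * np.exp(-lo_y ** 2 / (2 * s ** 2))
        model = A[:, None] * Ex * Ey + b[:, None]
        res = model - data
        J = np.stack([
            A[:, None] * (-(phi_ux - phi_lx)) * Ey,            # d/dx0
            A[:, None] * Ex * (-(phi_uy - phi_ly)),            # d/dy0
            Ex * Ey,                                            # d/dA
            np.ones_like(Ex),                                   # d/db
            A[:, None] * (-(up_x * phi_ux - lo_x * phi_lx) / s * Ey
                          - Ex * (up_y * phi_uy - lo_y * phi_ly) / s),
        ], axis=2)                                              # (n, px, 5)
        JTJ = np.einsum("npi,npj->nij", J, J)
        JTr = np.einsum("npi,np->ni", J, res)
        JTJ[:, np.arange(5), np.arange(5)] *= (1.0 + lam)
        JTJ[:, np.arange(5), np.arange(5)] += 1e-12
        try:
            delta = np.linalg.solve(JTJ, -JTr[..., None])[..., 0]
        except np.linalg.LinAlgError:   # pragma: no cover - degenerate window
            break
        x0 = np.clip(x0 + delta[:, 0], -r - 0.5, r + 0.5)
        y0 = np.clip(y0 + delta[:, 1], -r - 0.5, r + 0.5)
        A = np.clip(A + delta[:, 2], 1e-3, None)
        b = b + delta[:, 3]
        if fit_sigma:
            sig = np.clip(sig + delta[:, 4], 0.25, 4.0)
    out = np.stack([x0, y0, A, b, sig], axis=1)
    if not fit_sigma:
        # collapsed fits (amplitude driven to the clamp by an off-centre
        # blob in the tight window) fall back to the centroid route; in
        # larger windows collapsed fits are rare smear artefacts whose
        # clipped centroid would bias steps, so they are left as fitted
        bad = out[:, 2] <= 1.0
        if bad.any():
            out[bad] = _centroid_spots(windows[bad])
    return out


def _pixel_fraction(offsets: np.ndarray, sigma) -> np.ndarray:
    """Fraction of a unit-sigma-normalised Gaussian falling in unit pixels."""
    sq2 = np.sqrt(2.0)
    return 0.5 * (erf((offsets + 0.5) / (sq2 * sigma))
                  - erf((offsets - 0.5) / (sq2 * sigma)))


def detect_params_for(optical: OpticalTimingConfig,
                      d_um2_s: float | None = None) -> dict:
    """Detection parameters matched to the expected spot size.

    Motion blur during the exposure widens spots beyond the PSF by
    ``sqrt(D * dT_exp / 3)`` per axis; when the diffusion scale is known
    (e.g. from the FCS measurement, or the true value in a simulation
    study) the bandpass, merge separation and fit window follow it.
    """
    psf_px = optical.psf_sigma_um / optical.pixel_um
    blur_px = 0.0
    if d_um2_s is not None and d_um2_s > 0:
        blur_px = np.sqrt(d_um2_s * optical.exposure_s / 3.0) / optical.pixel_um
    sig = float(np.clip(np.hypot(psf_px, blur_px), 0.7, 2.0))
    # Single-fluorophore plausibility floor: at low blur a genuine emitter
    # concentrates >=50 detected photons in the fit window even at the rim,
    # so dimmer detections are noise or merge residue; heavy blur spreads
    # real spots thin, so no floor is applied there.
    if sig <= 0.75:
        min_photons = 50.0
    elif sig <= 1.0:
        min_photons = 30.0
    else:
        min_photons = 0.0
    return {"detect_sigma_px": sig,
            "min_sep_px": float(max(2.0, 2.5 * sig)),
            "window_radius": 1 if sig <= 0.75 else 2,
            "min_photons": min_photons}


def _centroid_spots(windows: np.ndarray) -> np.ndarray:
    """Background-subtracted intensity-weighted centroid (fallback route)."""
    n, w, _ = windows.shape
    r = w // 2
    c = np.arange(w, dtype=float) - r
    cx = np.broadcast_to(c[None, :], (w, w)).ravel()
    cy = np.broadcast_to(c[:, None], (w, w)).ravel()
    data = windows.reshape(n, -1).astype(float)
    edge = np.concatenate([windows[:, 0, :], windows[:, -1, :],
                           windows[:, :, 0], windows[:, :, -1]], axis=1)
    b = np.median(edge, axis=1)
    resid = np.clip(data - b[:, None], 0.0, None)
    tot = np.clip(resid.sum(axis=1), 1e-9, None)
    x0 = (resid * cx).sum(axis=1) / tot
    y0 = (resid * cy).sum(axis=1) / tot
    var = ((resid * (cx - x0[:, None]) ** 2).sum(axis=1) / tot
           + (resid * (cy - y0[:, None]) ** 2).sum(axis=1) / tot) / 2.0
    sig = np.sqrt(np.clip(var, 0.01, None))
    return np.stack([x0, y0, tot, b, sig], axis=1)


def _sigma_loc_um(width_px: np.ndarray, photons: np.ndarray,
                  background: np.ndarray, pixel_um: float) -> np.ndarray:
    """Per-spot localization uncertainty from photon statistics.

    Thompson-style shot-noise scaling for a least-squares Gaussian fit:
    ``sigma_a^2/N * 16/9 + 8 pi sigma_a^4 b / (a^2 N^2)`` with
    ``sigma_a^2 = width^2 + a^2/12`` (all in um) and ``b`` the background
    photons per pixel.
    """
    a = pixel_um
    sa2 = (width_px * a) ** 2 + a ** 2 / 12.0
    N = np.clip(photons, 1.0, None)
    bg = np.clip(background, 0.0, None)
    var = sa2 / N * (16.0 / 9.0) + 8.0 * np.pi * sa2 ** 2 * bg / (a ** 2 * N ** 2)
    return np.sqrt(var)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _neighbor_corrected_windows(data: np.ndarray, frames_arr: np.ndarray,
                                peaks: np.ndarray, p: np.ndarray,
                                wr: int) -> np.ndarray:
    """Windows with the fitted models of neighbouring spots subtracted.

    Crowded fields bias single-spot fits because neighbour light leaks
    into the window; a second fit pass on neighbour-subtracted windows
    (multi-emitter refinement) removes most of that pull.
    """
    H, W = data.shape[1:]
    win = 2 * wr + 1
    rp = wr + 3
    out = np.empty((len(p), win, win))
    for f in np.unique(frames_arr):
        idx = np.flatnonzero(frames_arr == f)
        model = np.zeros((H, W))
        x0 = peaks[idx, 0] + 0.5 + p[idx, 0]
        y0 = peaks[idx, 1] + 0.5 + p[idx, 1]
        for k, i in enumerate(idx):
            cx, cy = int(peaks[i, 0]), int(peaks[i, 1])
            xs = np.arange(max(cx - rp, 0), min(cx + rp + 1, W))
            ys = np.arange(max(cy - rp, 0), min(cy + rp + 1, H))
            ex = _pixel_fraction(xs + 0.5 - x0[k], p[i, 4])
            ey = _pixel_fraction(ys + 0.5 - y0[k], p[i, 4])
            model[np.ix_(ys, xs)] += p[i, 2] * ey[:, None] * ex[None, :]
        for k, i in enumerate(idx):
            cx, cy = int(peaks[i, 0]), int(peaks[i, 1])
            xs = np.arange(cx - wr, cx + wr + 1)
            ys = np.arange(cy - wr, cy + wr + 1)
            ex = _pixel_fraction(xs + 0.5 - x0[k], p[i, 4])
            ey = _pixel_fraction(ys + 0.5 - y0[k], p[i, 4])
            own = p[i, 2] * ey[:, None] * ex[None, :]
            raw = data[f, cy - wr:cy + wr + 1, cx - wr:cx + wr + 1]
            out[i] = raw - model[np.ix_(ys, xs)] + own
    return out


def detect_spots(stack: ImageStack, threshold_k: float = 5.0,
                 detect_sigma_px: float = 1.5, min_sep_px: float = 3.0,
                 window_radius: int = 2, refine: str = "gauss",
                 neighbor_subtraction: bool = True,
                 min_photons: float = 0.0,
                 counts_per_photon: float = 1.0) -> pd.DataFrame:
    """Detect diffraction-limited spots in every frame of a stack.

    Returns a DataFrame with columns ``frame, x_um, y_um, intensity``
    (integrated photons), ``width_px`` (fitted Gaussian sigma),
    ``sigma_loc_um`` and ``background``.  An empty result is valid.
    Saturated or constant frames are skipped and counted in
    ``df.attrs["flagged_frames"]``.
    """
    if refine not in ("gauss", "centroid"):
        raise ValueError("refine must be 'gauss' or 'centroid'")
    data = stack.data
    if data.shape[0] == 0:
        raise ValueError("empty stack")
    optical = stack.optical
    H, W = data.shape[1:]
    s1 = detect_sigma_px
    s2 = 2.5 * detect_sigma_px
    wr = int(window_radius)
    win = 2 * wr + 1

    frames_idx: list[np.ndarray] = []
    peaks_xy: list[np.ndarray] = []
    windows: list[np.ndarray] = []
    flagged = 0
    for f in range(data.shape[0]):
        img = data[f].astype(float)
        if img.max() == img.min() or img.max() >= 65535:
            flagged += 1
            if img.max() == img.min():
                continue
        bp = ndimage.gaussian_filter(img, s1) - ndimage.gaussian_filter(img, s2)
        med = np.median(bp)
        mad = np.median(np.abs(bp - med))
        thr = med + threshold_k * 1.4826 * mad
        local_max = bp == ndimage.maximum_filter(bp, size=3)
        ys, xs = np.nonzero(local_max & (bp > thr))
        if len(xs) == 0:
            continue
        vals = bp[ys, xs]
        # merge candidates closer than min_sep, keeping the brighter one
        order = np.argsort(-vals)
        ys, xs, vals = ys[order], xs[order], vals[order]
        keep = np.ones(len(xs), dtype=bool)
        for i in range(len(xs)):
            if not keep[i]:
                continue
            d2 = (xs[i + 1:] - xs[i]) ** 2 + (ys[i + 1:] - ys[i]) ** 2
            keep[i + 1:] &= d2 >= min_sep_px ** 2
        ys, xs = ys[keep], xs[keep]
        inside = (xs >= wr) & (xs < W - wr) & (ys >= wr) & (ys < H - wr)
        ys, xs = ys[inside], xs[inside]
        if len(xs) == 0:
            continue
        w = np.stack([data[f, y - wr:y + wr + 1, x - wr:x + wr + 1]
                      for y, x in zip(ys, xs)])
        frames_idx.append(np.full(len(xs), f))
        peaks_xy.append(np.stack([xs, ys], axis=1))
        windows.append(w)

    if not windows:
        df = pd.DataFrame(columns=SPOT_COLUMNS)
        df.attrs["n_frames"] = data.shape[0]
        df.attrs["flagged_frames"] = flagged
        return df

    frames_arr = np.concatenate(frames_idx)
    peaks = np.concatenate(peaks_xy).astype(float)
    wins = np.concatenate(windows).astype(float)

    sigma0 = max(optical.psf_sigma_um / optical.pixel_um, 0.5)

    def batched_fit(w):
        if refine == "gauss":
            # a 3x3 window cannot support a free width: freeze it
            def fitfun(v):
                return _fit_gaussian_spots(v, sigma0, fit_sigma=wr >= 2)
        else:
            fitfun = _centroid_spots
        chunk = 50_000
        return np.concatenate([fitfun(w[i0:i0 + chunk])
                               for i0 in range(0, len(w), chunk)])

    p = batched_fit(wins)
    if refine == "gauss" and neighbor_subtraction:
        wins2 = _neighbor_corrected_windows(data, frames_arr, peaks, p, wr)
        p = batched_fit(wins2)

    x_px = peaks[:, 0] + 0.5 + p[:, 0]
    y_px = peaks[:, 1] + 0.5 + p[:, 1]
    photons = p[:, 2] / counts_per_photon
    bg_photons = p[:, 3] / counts_per_photon
    sigma_loc = _sigma_loc_um(p[:, 4], photons, bg_photons, optical.pixel_um)

    df = pd.DataFrame({
        "frame": frames_arr.astype(int),
        "x_um": (x_px - W / 2.0) * optical.pixel_um,
        "y_um": (y_px - H / 2.0) * optical.pixel_um,
        "intensity": photons,
        "width_px": p[:, 4],
        "sigma_loc_um": sigma_loc,
        "background": bg_photons,
    }).sort_values(["frame", "x_um"], kind="stable").reset_index(drop=True)
    if min_photons > 0:
        df = df[df["intensity"] >= min_photons].reset_index(drop=True)
    df.attrs["n_frames"] = data.shape[0]
    df.attrs["flagged_frames"] = flagged
    df.attrs["refine"] = refine
    return df


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

@dataclass
class TrackSet:
    """Linked trajectories: a spot table with a ``track_id`` column.

    Frames within a trajectory are strictly consecutive and every
    consecutive displacement is at most the MLR.
    """

    df: pd.DataFrame
    mlr_um: float
    n_dropped_short: int = 0

    @property
    def n_tracks(self) -> int:
        return self.df["track_id"].nunique()

    def steps(self) -> pd.DataFrame:
        """Lag-1 steps: one row per consecutive-frame displacement."""
        g = self.df.sort_values(["track_id", "frame"])
        dx = g.groupby("track_id")["x_um"].diff()
        dy = g.groupby("track_id")["y_um"].diff()
        out = pd.DataFrame({"track_id": g["track_id"], "frame": g["frame"],
                            "dx_um": dx, "dy_um": dy})
        out = out.dropna()
        out["sd_um2"] = out["dx_um"] ** 2 + out["dy_um"] ** 2
        return out.reset_index(drop=True)

    def track_arrays(self):
        """Yield ``(track_id, (n, 2) position array)`` per trajectory."""
        for tid, g in self.df.groupby("track_id"):
            yield tid, g.sort_values("frame")[["x_um", "y_um"]].to_numpy()


def _pair_costs(p1: np.ndarray, p2: np.ndarray, i1: np.ndarray,
                i2: np.ndarray, cfg: LinkConfig) -> np.ndarray:
    d2 = ((p1[:, None, :] - p2[None, :, :]) ** 2).sum(axis=2)
    if cfg.intensity_weight > 0:
        rel = np.abs(i1[:, None] - i2[None, :]) / \
            np.clip(i1[:, None] + i2[None, :], 1e-9, None)
        d2 = d2 * (1.0 + cfg.intensity_weight * rel)
    cost = np.where(d2 <= cfg.mlr_um ** 2, d2, _BIG)
    return cost


def link_spots(spots: pd.DataFrame, cfg: LinkConfig,
               min_track_len: int = 2) -> TrackSet:
    """Link detected spots into trajectories by LAP minimisation.

    Per consecutive frame pair a square cost matrix couples links (squared
    displacement, forbidden beyond the MLR), deaths and births (cost
    ``MLR^2`` each); ``scipy.optimize.linear_sum_assignment`` finds the
    global per-pair optimum.  Trajectories shorter than ``min_track_len``
    spots are dropped (count reported on the result).
    """
    spots = spots.sort_values(["frame"], kind="stable").reset_index(drop=True)
    n = len(spots)
    track_id = np.full(n, -1, dtype=np.int64)
    if n == 0:
        ts = TrackSet(df=spots.assign(track_id=np.array([], dtype=np.int64)),
                      mlr_um=cfg.mlr_um)
        return ts
    frames = spots["frame"].to_numpy()
    xy = spots[["x_um", "y_um"]].to_numpy()
    inten = spots["intensity"].to_numpy() if "intensity" in spots else \
        np.ones(n)
    open_cost = cfg.open_cost

    by_frame: dict[int, np.ndarray] = {
        int(f): np.flatnonzero(frames == f) for f in np.unique(frames)}
    f_min, f_max = int(frames.min()), int(frames.max())

    next_id = 0
    prev_idx = by_frame.get(f_min, np.array([], dtype=int))
    for i in prev_idx:
        track_id[i] = next_id
        next_id += 1
    for f in range(f_min, f_max):
        cur = prev_idx
        nxt = by_frame.get(f + 1, np.array([], dtype=int))
        n1, n2 = len(cur), len(nxt)
        linked_next = np.zeros(n2, dtype=bool)
        if n1 > 0 and n2 > 0:
            tl = _pair_costs(xy[cur], xy[nxt], inten[cur], inten[nxt], cfg)
            size = n1 + n2
            C = np.full((size, size), _BIG)
            C[:n1, :n2] = tl
            C[np.arange(n1), n2 + np.arange(n1)] = open_cost
            C[n1 + np.arange(n2), np.arange(n2)] = open_cost
            C[n1:, n2:] = np.where(tl.T < _BIG, 0.0, _BIG)
            rows, cols = linear_sum_assignment(C)
            for r_, c_ in zip(rows, cols):
                if r_ < n1 and c_ < n2 and tl[r_, c_] < _BIG:
                    track_id[nxt[c_]] = track_id[cur[r_]]
                    linked_next[c_] = True
        for j in np.flatnonzero(~linked_next):
            track_id[nxt[j]] = next_id
            next_id += 1
        prev_idx = nxt

    out = spots.assign(track_id=track_id)
    sizes = out.groupby("track_id")["frame"].size()
    good = sizes.index[sizes >= min_track_len]
    dropped = int(len(sizes) - len(good))
    out = out[out["track_id"].isin(good)]
    out = out.sort_values(["track_id", "frame"]).reset_index(drop=True)
    return TrackSet(df=out, mlr_um=cfg.mlr_um, n_dropped_short=dropped)


# ---------------------------------------------------------------------------
# localization uncertainty and density diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocalizationSigma:
    sigma_um: float
    method: str     # "empirical" | "photon"
    n: int


def estimate_localization_sigma(stack: ImageStack | None = None,
                                spots: pd.DataFrame | None = None,
                                **detect_kwargs) -> LocalizationSigma:
    """Estimate the static localization uncertainty sigma_loc.

    Empirical route (preferred when a ``D = 0`` calibration stack is
    available): repeatedly localize the immobile emitters and report the
    per-axis standard deviation of the fitted positions.  Photon route:
    median of the per-spot shot-noise formula already attached by
    :func:`detect_spots`.
    """
    if stack is not None:
        found = detect_spots(stack, **detect_kwargs)
        if len(found) < 20:
            raise ValueError("need >= 20 localizations of immobile emitters")
        # cluster detections of the same emitter by rounding to a 2-px grid
        grid = 2.0 * stack.optical.pixel_um
        key = (np.round(found["x_um"] / grid).astype(int) * 100003
               + np.round(found["y_um"] / grid).astype(int))
        found = found.assign(_k=key)
        sds = []
        for _, g in found.groupby("_k"):
            if len(g) >= 5:
                sds.append(g["x_um"].std(ddof=1))
                sds.append(g["y_um"].std(ddof=1))
        if not sds:
            raise ValueError("no emitter was localized repeatedly")
        return LocalizationSigma(float(np.mean(sds)), "empirical", len(found))
    if spots is not None and len(spots):
        return LocalizationSigma(float(np.median(spots["sigma_loc_um"])),
                                 "photon", len(spots))
    raise ValueError("provide a calibration stack or a spot table")


def apparent_density(spots: pd.DataFrame, illuminated_area_um2: float,
                     n_frames: int | None = None) -> float:
    """Mean detected spots per frame divided by the illuminated area."""
    if illuminated_area_um2 <= 0:
        raise ValueError("area must be > 0")
    if n_frames is None:
        n_frames = spots.attrs.get("n_frames")
    if n_frames is None:
        if len(spots) == 0:
            return 0.0
        n_frames = int(spots["frame"].max()) + 1
    if n_frames <= 0:
        raise ValueError("zero frames")
    return len(spots) / n_frames / illuminated_area_um2
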