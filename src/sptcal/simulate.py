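"""Brownian-motion microscopy simulator.

Generates ground-truth 2D Brownian trajectories of fluorescent lipids in a
planar bilayer and renders them either as widefield EMCCD image stacks
(circularly-masked Gaussian illumination, Gaussian PSF, motion blur over the
camera exposure, photobleaching with an exponential photon budget, detector
noise) or as confocal photon-count traces crossing a Gaussian detection
profile.

Layout of the trajectory arrays: particle positions are stored only at the
midpoints of the ``substeps_per_frame`` sub-exposures of each frame; the
dead time between exposure end and the next frame start contributes motion
but no photons.  All randomness flows from a single seed through
``numpy.random.SeedSequence`` spawning, so identical configuration + seed
reproduces bit-identical output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import EmitterModel, OpticalTimingConfig, SampleConfig

__all__ = [
    "GroundTruth",
    "ImageStack",
    "PhotonTrace",
    "simulate_positions",
    "render_stack",
    "simulate_confocal_trace",
]


class SimulationSizeError(ValueError):
    """Particle count exceeds the configured resource cap."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """True trajectories underlying a rendered movie.

    ``positions`` has shape ``(n_substeps, n_particles, 2)`` (um, origin at
    the illumination centre).  Positions are stored *unwrapped* (continuous
    walks); the periodic boundary of the simulation domain is applied when
    photons are emitted, so exposure averages and increments are artefact
    free.  Entries are NaN before a replenished particle has been spawned.  ``frame_photons`` and ``bleach_time_s`` are filled in
    by :func:`render_stack`.
    """

    positions: np.ndarray            # (S, N, 2) float32, um
    times_s: np.ndarray              # (S,) substep midpoint times
    substeps_per_frame: int
    n_frames: int
    domain_um: float                 # periodic square side length
    sample: SampleConfig
    optical: OpticalTimingConfig
    frame_photons: Optional[np.ndarray] = None   # (n_frames, N)
    bleach_time_s: Optional[np.ndarray] = None   # (N,), inf = never
    particle_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.particle_ids is None:
            self.particle_ids = np.arange(self.positions.shape[1])

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def frame_positions(self) -> np.ndarray:
        """Exposure-averaged (motion-blur centroid) position per frame."""
        S = self.n_frames * self.substeps_per_frame
        p = self.positions[:S].reshape(self.n_frames, self.substeps_per_frame,
                                       self.n_particles, 2)
        return p.mean(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy per-frame table (particle_id, frame, x_um, y_um, photons)."""
        fp = self.frame_positions
        n_f, n_p = fp.shape[:2]
        photons = (self.frame_photons if self.frame_photons is not None
                   else np.zeros((n_f, n_p)))
        frame, pid = np.meshgrid(np.arange(n_f), self.particle_ids,
                                 indexing="ij")
        df = pd.DataFrame({
            "particle_id": pid.ravel(),
            "frame": frame.ravel(),
            "x_um": fp[..., 0].ravel(),
            "y_um": fp[..., 1].ravel(),
            "photons": photons.ravel(),
        })
        return df[np.isfinite(df["x_um"])].reset_index(drop=True)


@dataclass
class ImageStack:
    """Rendered widefield movie: ``(n_frames, H, W)`` photon-count images."""

    data: np.ndarray
    optical: OpticalTimingConfig
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("ImageStack data must be (frames, H, W)")
        if self.data.shape[0] != self.optical.n_frames:
            raise ValueError("frame count does not match optical.n_frames")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass
class PhotonTrace:
    """Binned confocal photon counts at fixed dwell time."""

    counts: np.ndarray
    dwell_s: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be nonnegative")

    @property
    def duration_s(self) -> float:
        return len(self.counts) * self.dwell_s


# ---------------------------------------------------------------------------
# trajectory generation
# ---------------------------------------------------------------------------

def _substep_times(optical: OpticalTimingConfig, n_sub: int) -> np.ndarray:
    """Midpoint times of the exposure substeps of every frame."""
    dt = optical.exposure_s / n_sub
    k = np.arange(n_sub) + 0.5
    f = np.arange(optical.n_frames)[:, None] * optical.frame_interval_s
    return (f + k[None, :] * dt).ravel()


def _wrap(x: np.ndarray, half: float) -> np.ndarray:
    return (x + half) % (2 * half) - half


def simulate_positions(sample: SampleConfig, optical: OpticalTimingConfig,
                       substeps_per_frame: int = 10, margin_um: float = 20.0,
                       max_particles: int = 20000,
                       rng: np.random.Generator | None = None) -> GroundTruth:
    """Simulate 2D Brownian motion on a periodic square domain.

    The domain side is the mask diameter plus ``margin_um`` so the emitting
    density inside the illuminated disc stays stationary (particles leave
    and enter by diffusion; periodic wrap conserves their number).  The
    particle count is Poisson at ``density * area`` unless
    ``sample.n_particles`` pins it.
    """
    if substeps_per_frame < 1:
        raise ValueError("substeps_per_frame must be >= 1")
    if optical.n_frames <= 0:
        raise ValueError("n_frames must be positive")
    rng = np.random.default_rng(sample.seed) if rng is None else rng

    L = optical.mask_diameter_um + margin_um
    half = L / 2.0
    init = None
    if sample.init_positions_um is not None:
        init = np.asarray(sample.init_positions_um, dtype=float).reshape(-1, 2)
        n = len(init)
    elif sample.n_particles is not None:
        n = int(sample.n_particles)
    else:
        n = int(rng.poisson(sample.density_um2 * L * L))
    if n > max_particles:
        raise SimulationSizeError(
            f"{n} particles exceeds the cap of {max_particles}; lower the "
            "density or raise max_particles")

    times = _substep_times(optical, substeps_per_frame)
    S = len(times)
    deltas = np.diff(times)
    pos = np.empty((S, n, 2), dtype=np.float32)
    pos[0] = init if init is not None else rng.uniform(-half, half, size=(n, 2))
    if sample.diffusion_um2_s > 0 and n > 0:
        sigmas = np.sqrt(2.0 * sample.diffusion_um2_s * deltas)
        # chunked accumulation keeps memory flat for long movies
        step = 2000
        prev = pos[0].astype(np.float64)
        for s0 in range(1, S, step):
            s1 = min(s0 + step, S)
            incr = rng.normal(size=(s1 - s0, n, 2)) \
                * sigmas[s0 - 1:s1 - 1, None, None]
            block = prev + np.cumsum(incr, axis=0)
            pos[s0:s1] = block.astype(np.float32)
            prev = block[-1]
    else:
        pos[1:] = pos[0]

    return GroundTruth(positions=pos, times_s=times,
                       substeps_per_frame=substeps_per_frame,
                       n_frames=optical.n_frames, domain_um=L,
                       sample=sample, optical=optical)


# ---------------------------------------------------------------------------
# widefield rendering
# ---------------------------------------------------------------------------

def _emission_counts(pos: np.ndarray, times: np.ndarray,
                     optical: OpticalTimingConfig, emitter: EmitterModel,
                     rng: np.random.Generator, budget: np.ndarray,
                     domain_half: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-substep Poisson photon counts, capped by exponential budgets.

    Returns ``(counts (S,N) uint32, bleach_time_s (N,))``.
    """
    S, N = pos.shape[:2]
    dt = optical.exposure_s / int(round(S / optical.n_frames)) \
        if optical.n_frames else optical.exposure_s
    # dt is constant across exposure substeps by construction; positions
    # are unwrapped walks, so apply the periodic domain here
    wrapped = _wrap(pos, domain_half)
    illum = optical.illumination(wrapped[..., 0], wrapped[..., 1])
    illum = np.nan_to_num(illum, nan=0.0)
    lam = emitter.peak_photon_rate * dt * illum
    counts = rng.poisson(lam).astype(np.int64)
    bleach = np.full(N, np.inf)
    if np.isfinite(budget).any():
        cum = np.cumsum(counts, axis=0)
        over = cum > budget[None, :]
        hit = over.any(axis=0)
        idx = np.argmax(over, axis=0)
        for j in np.flatnonzero(hit):
            s = idx[j]
            remainder = int(budget[j] - (cum[s, j] - counts[s, j]))
            counts[s, j] = max(remainder, 0)
            counts[s + 1:, j] = 0
            bleach[j] = times[s]
    return counts.astype(np.uint32), bleach


def render_stack(truth: GroundTruth, optical: OpticalTimingConfig,
                 emitter: EmitterModel, seed: int = 0) -> ImageStack:
    """Render ground-truth trajectories into an EMCCD image stack.

    Per exposure substep each live emitter draws Poisson photons at
    ``peak_photon_rate`` scaled by the masked-Gaussian illumination at its
    position; photon impact points are the emitter position plus Gaussian
    PSF scatter, binned into pixels.  Cumulative emission is capped by an
    exponential photon budget (photobleaching); with ``sample.replenish``
    each bleached emitter is replaced by a fresh one spawned uniformly in
    the illuminated disc (the much larger membrane acts as an effectively
    unbleached reservoir), keeping the emitting density stationary.  Camera
    noise: Poisson signal and background, optional gamma EM excess noise,
    gain, Gaussian read noise.

    ``truth`` is augmented in place with per-frame photon counts, bleach
    times and any replenished particles.
    """
    if truth.n_frames != optical.n_frames:
        raise ValueError("truth and optical disagree on n_frames")
    ss = np.random.SeedSequence(seed)
    rng_phot, rng_place, rng_noise, rng_spawn = \
        [np.random.default_rng(s) for s in ss.spawn(4)]

    n_sub = truth.substeps_per_frame
    S = truth.n_frames * n_sub
    pos = truth.positions[:S]
    N0 = pos.shape[1]
    times = truth.times_s[:S]
    half = truth.domain_um / 2.0
    mean_budget = emitter.bleach_mean_photons

    def draw_budget(rng, size):
        if math.isinf(mean_budget):
            return np.full(size, np.inf)
        return rng.exponential(mean_budget, size)

    counts, bleach = _emission_counts(pos, times, optical, emitter, rng_phot,
                                      draw_budget(rng_phot, N0), half)

    # --- replenishment: respawn bleached emitters outside the mask --------
    positions_all = [pos]
    counts_all = [counts]
    bleach_all = [bleach]
    if truth.sample.replenish and np.isfinite(bleach).any():
        dt = optical.exposure_s / n_sub
        D = truth.sample.diffusion_um2_s
        queue = [int(np.searchsorted(times, b, side="right"))
                 for b in bleach[np.isfinite(bleach)]]
        while queue:
            s0 = queue.pop()
            if s0 >= S - 1:
                continue
            # spawn uniformly inside the illuminated disc: emulates the
            # effectively unbleached reservoir of the much larger membrane,
            # keeping the emitting density in the disc stationary
            while True:
                p0 = rng_spawn.uniform(-optical.mask_radius_um,
                                       optical.mask_radius_um, size=2)
                if p0[0] ** 2 + p0[1] ** 2 <= optical.mask_radius_um ** 2:
                    break
            n_rem = S - s0
            deltas = np.diff(times[s0:])
            walk = np.empty((n_rem, 2), dtype=np.float32)
            walk[0] = p0
            if D > 0:
                incr = rng_spawn.normal(size=(n_rem - 1, 2)) \
                    * np.sqrt(2 * D * deltas)[:, None]
                walk[1:] = p0 + np.cumsum(incr, axis=0)
            else:
                walk[1:] = p0
            full = np.full((S, 1, 2), np.nan, dtype=np.float32)
            full[s0:, 0] = walk
            c, b = _emission_counts(full, times, optical, emitter, rng_spawn,
                                    draw_budget(rng_spawn, 1), half)
            positions_all.append(full)
            counts_all.append(c)
            bleach_all.append(b)
            if np.isfinite(b[0]):
                queue.append(int(np.searchsorted(times, b[0], side="right")))

    pos = np.concatenate(positions_all, axis=1)
    counts = np.concatenate(counts_all, axis=1)
    bleach = np.concatenate(bleach_all)
    Nall = pos.shape[1]

    truth.positions = pos
    truth.bleach_time_s = bleach
    truth.particle_ids = np.arange(Nall)
    truth.frame_photons = counts.reshape(truth.n_frames, n_sub, Nall) \
                                .sum(axis=1)

    # --- rasterise photons frame by frame ----------------------------------
    H, W = optical.image_dim_px
    px = optical.pixel_um
    sigma = optical.psf_sigma_um
    frames = np.empty((truth.n_frames, H, W), dtype=np.uint16)
    gain = emitter.em_gain
    pos_f = pos.reshape(truth.n_frames, n_sub, Nall, 2)
    counts_f = counts.reshape(truth.n_frames, n_sub, Nall)
    for f in range(truth.n_frames):
        c = counts_f[f].ravel()
        img = np.zeros(H * W)
        m = c > 0
        if m.any():
            origins = _wrap(pos_f[f].reshape(-1, 2)[m], half)
            origins = np.repeat(origins, c[m], axis=0)
            pts = origins + rng_place.normal(0.0, sigma, origins.shape)
            ix = np.floor(pts[:, 0] / px + W / 2.0).astype(np.int64)
            iy = np.floor(pts[:, 1] / px + H / 2.0).astype(np.int64)
            ok = (ix >= 0) & (ix < W) & (iy >= 0) & (iy < H)
            img = np.bincount(iy[ok] * W + ix[ok], minlength=H * W) \
                .astype(np.float64)
        if emitter.background_rate > 0:
            img = img + rng_noise.poisson(emitter.background_rate, H * W)
        if emitter.em_excess_noise:
            nz = img > 0
            amp = np.zeros_like(img)
            amp[nz] = rng_noise.gamma(img[nz], gain)
            img = amp
        else:
            img = img * gain
        if emitter.read_noise_sd > 0:
            img = img + rng_noise.normal(0.0, emitter.read_noise_sd, H * W)
        frames[f] = np.clip(np.rint(img), 0, 65535).reshape(H, W)

    meta = {"seed": seed, "diffusion_um2_s": truth.sample.diffusion_um2_s,
            "density_um2": truth.sample.density_um2,
            "n_particles": int(Nall)}
    return ImageStack(data=frames, optical=optical, meta=meta)


# ---------------------------------------------------------------------------
# confocal trace
# ---------------------------------------------------------------------------

def simulate_confocal_trace(sample: SampleConfig, optical: OpticalTimingConfig,
                            emitter: EmitterModel | None = None,
                            duration_s: float = 60.0, box_um: float = 20.0,
                            background_hz: float = 200.0,
                            seed: int | None = None) -> PhotonTrace:
    """Simulate binned photon counts from particles crossing the confocal spot.

    Per dwell bin the detected intensity is the sum over particles of
    ``peak_photon_rate * exp(-2 r^2 / omega1^2)`` plus background; counts
    are Poisson.  No photobleaching (negligible at FCS powers).  The
    particle count is fixed at ``round(density * box^2)`` on a periodic box
    centred on the detection spot.
    """
    emitter = EmitterModel.confocal_default() if emitter is None else emitter
    rng = np.random.default_rng(sample.seed if seed is None else seed)
    dwell = optical.dwell_s
    D = sample.diffusion_um2_s
    w2 = optical.omega1_um ** 2
    if D > 0:
        crossing = w2 / (4.0 * D)
        if dwell > crossing / 10.0:
            warnings.warn("dwell time is not small versus the crossing time "
                          f"omega1^2/4D = {crossing:.2e} s", stacklevel=2)
        if duration_s < 100.0 * crossing:
            warnings.warn("trace shorter than 100 crossing times; "
                          "correlation statistics will be poor", stacklevel=2)

    n_bins = int(round(duration_s / dwell))
    half = box_um / 2.0
    n = int(round(sample.density_um2 * box_um * box_um)) \
        if sample.n_particles is None else int(sample.n_particles)
    counts = np.empty(n_bins, dtype=np.int64)
    if sample.init_positions_um is not None:
        pos = np.asarray(sample.init_positions_um, dtype=float).reshape(-1, 2)
        n = len(pos)
    else:
        pos = rng.uniform(-half, half, size=(n, 2))
    step_sd = math.sqrt(2.0 * D * dwell)
    chunk = 200_000
    for b0 in range(0, n_bins, chunk):
        b1 = min(b0 + chunk, n_bins)
        m = b1 - b0
        if n > 0:
            if step_sd > 0:
                incr = rng.normal(0.0, step_sd, size=(m, n, 2))
                walk = _wrap(pos + np.cumsum(incr, axis=0), half)
                pos = walk[-1]
            else:
                walk = np.broadcast_to(pos, (m, n, 2))
            r2 = walk[..., 0] ** 2 + walk[..., 1] ** 2
            rate = emitter.peak_photon_rate * np.exp(-2.0 * r2 / w2)
            lam = rate.sum(axis=1) * dwell
        else:
            lam = np.zeros(m)
        counts[b0:b1] = rng.poisson(lam + background_hz * dwell)
    meta = {"n_particles": n, "box_um": box_um, "background_hz": background_hz,
            "diffusion_um2_s": D, "density_um2": sample.density_um2}
    return PhotonTrace(counts=counts, dwell_s=dwell, meta=meta)
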