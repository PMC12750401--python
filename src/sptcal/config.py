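"""Configuration objects for the simulator, tracker and analysis pipeline.

All lengths are carried in the units the instrument reports them in (nm for
optical scales, um for positions, ms for camera timing) and converted through
explicit properties.  Positions everywhere in the package are continuous
micrometres with the origin at the centre of the illuminated disc; pixel *i*
covers ``[i, i+1)`` in pixel units so pixel centres sit at half-integer pixel
coordinates.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates an invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass(frozen=True)
class OpticalTimingConfig:
    """Optics and camera timing of the dual-mode microscope.

    Defaults replicate the apparatus: 336 nm px-1 after 2x2 binning, a
    Gaussian PSF of ~280 nm 1/e^2 radius, a ~37 um diameter circularly-masked
    Gaussian illumination profile (~1100 um^2), 40 ms exposure at a 42 ms
    frame interval, and a confocal detection profile of 1/e^2 radius
    omega_1 = 312 nm.
    """

    pixel_size_nm: float = 336.0
    image_dim_px: tuple[int, int] = (128, 128)
    psf_radius_nm: float = 280.0          # 1/e^2 radius; sigma = radius / 2
    mask_diameter_um: float = 37.0
    illum_gauss_width_um: float = 37.0    # 1/e^2 radius of the unmasked beam
    exposure_ms: float = 40.0
    frame_interval_ms: float = 42.0
    n_frames: int = 1000
    omega1_nm: float = 312.0
    dwell_us: float = 10.0

    def __post_init__(self) -> None:
        _require(self.exposure_ms > 0, "exposure_ms must be > 0")
        _require(self.frame_interval_ms >= self.exposure_ms,
                 "frame_interval_ms must be >= exposure_ms")
        for name in ("pixel_size_nm", "psf_radius_nm", "mask_diameter_um",
                     "illum_gauss_width_um", "omega1_nm", "dwell_us"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(self.n_frames > 0, "n_frames must be > 0")
        h, w = self.image_dim_px
        _require(h > 0 and w > 0, "image_dim_px must be positive")
        fov = min(h, w) * self.pixel_size_nm / 1000.0
        _require(self.mask_diameter_um <= fov,
                 f"illumination mask ({self.mask_diameter_um} um) does not fit "
                 f"inside the {fov:.1f} um field of view")

    # -- derived quantities -------------------------------------------------
    @property
    def pixel_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def psf_sigma_um(self) -> float:
        return self.psf_radius_nm / 2.0 / 1000.0

    @property
    def mask_radius_um(self) -> float:
        return self.mask_diameter_um / 2.0

    @property
    def illuminated_area_um2(self) -> float:
        return math.pi * self.mask_radius_um ** 2

    @property
    def exposure_s(self) -> float:
        return self.exposure_ms / 1000.0

    @property
    def frame_interval_s(self) -> float:
        return self.frame_interval_ms / 1000.0

    @property
    def dwell_s(self) -> float:
        return self.dwell_us * 1e-6

    @property
    def omega1_um(self) -> float:
        return self.omega1_nm / 1000.0

    @property
    def fov_um(self) -> tuple[float, float]:
        h, w = self.image_dim_px
        return (h * self.pixel_um, w * self.pixel_um)

    def illumination(self, x_um, y_um):
        """Relative illumination intensity at (x, y): masked 2D Gaussian.

        ``exp(-2 r^2 / w^2)`` inside the hard-edged circular mask, zero
        outside; normalised to 1 at the beam centre.
        """
        import numpy as np

        r2 = np.asarray(x_um) ** 2 + np.asarray(y_um) ** 2
        w2 = self.illum_gauss_width_um ** 2
        out = np.exp(-2.0 * r2 / w2)
        return np.where(r2 <= self.mask_radius_um ** 2, out, 0.0)


@dataclass(frozen=True)
class EmitterModel:
    """Photophysics of the fluorescent lipid and the EMCCD noise model.

    ``peak_photon_rate`` is the detected photon rate (s^-1) for an emitter
    sitting at the illumination maximum.  The total photon budget before
    photobleaching is exponential with mean ``bleach_mean_photons``
    (``inf`` disables bleaching).  Camera noise: Poisson signal, optional
    gamma-distributed EM excess noise, Gaussian read noise, gain applied
    last.
    """

    peak_photon_rate: float = 5000.0
    bleach_mean_photons: float = 6000.0
    background_rate: float = 2.0      # photons px^-1 frame^-1 (widefield)
    read_noise_sd: float = 1.0        # counts
    em_gain: float = 1.0
    em_excess_noise: bool = False

    def __post_init__(self) -> None:
        for name in ("peak_photon_rate", "background_rate", "read_noise_sd"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(self.bleach_mean_photons > 0, "bleach_mean_photons must be > 0")
        _require(self.em_gain > 0, "em_gain must be > 0")

    @classmethod
    def confocal_default(cls) -> "EmitterModel":
        """Bright, non-bleaching emitter for the low-power confocal mode."""
        return cls(peak_photon_rate=5.0e4, bleach_mean_photons=math.inf,
                   background_rate=0.0, read_noise_sd=0.0)


@dataclass(frozen=True)
class SampleConfig:
    """The bilayer sample: diffusion constant and label surface density."""

    diffusion_um2_s: float = 11.0
    density_um2: float = 0.035
    seed: int = 0
    replenish: bool = False
    n_particles: int | None = None    # override the Poisson draw (tests, dilute fixtures)
    init_positions_um: tuple | None = None   # pin initial positions ((x, y), ...)

    def __post_init__(self) -> None:
        _require(self.diffusion_um2_s >= 0, "diffusion_um2_s must be >= 0")
        _require(self.density_um2 >= 0, "density_um2 must be >= 0")
        if self.n_particles is not None:
            _require(self.n_particles >= 0, "n_particles must be >= 0")


@dataclass(frozen=True)
class LinkConfig:
    """Frame-to-frame linker settings.

    The link range is fixed at one frame (no gap closing): trajectories in
    these bilayers show no blinking.  Births and deaths cost ``mlr_um**2``
    unless overridden, the standard linear-assignment convention.
    """

    mlr_um: float = 2.3
    link_range_frames: int = 1
    birth_death_cost: float | None = None
    intensity_weight: float = 0.0

    def __post_init__(self) -> None:
        _require(self.mlr_um > 0, "mlr_um must be > 0")
        _require(self.link_range_frames == 1,
                 "link_range_frames is fixed at 1 (no gap closing)")
        _require(self.intensity_weight >= 0, "intensity_weight must be >= 0")

    @property
    def open_cost(self) -> float:
        return self.mlr_um ** 2 if self.birth_death_cost is None else self.birth_death_cost


@dataclass(frozen=True)
class TimingInfo:
    """Camera timing needed by the blur-corrected diffusion estimators."""

    frame_interval_s: float = 0.042
    exposure_s: float = 0.040

    def __post_init__(self) -> None:
        _require(self.exposure_s > 0, "exposure_s must be > 0")
        _require(self.frame_interval_s >= self.exposure_s,
                 "frame_interval_s must be >= exposure_s")

    @classmethod
    def from_optical(cls, optical: OpticalTimingConfig) -> "TimingInfo":
        return cls(frame_interval_s=optical.frame_interval_s,
                   exposure_s=optical.exposure_s)


@dataclass(frozen=True)
class AnalysisConfig:
    """Trajectory-analysis options shared by the CLI and pipelines."""

    method: str = "ss"                # "ss" | "ap"
    sigma_loc_um: float | None = None  # None -> estimate from photon counts
    bin_width_decades: float = 0.1
    min_positive_estimates: int = 30
    ap_max_lag: int = 10
    threshold_k: float = 5.0

    def __post_init__(self) -> None:
        _require(self.method in ("ss", "ap"), "method must be 'ss' or 'ap'")
        _require(self.bin_width_decades > 0, "bin_width_decades must be > 0")


@dataclass
class RunConfig:
    """Top-level run configuration: nested sections plus seed and paths."""

    optical: OpticalTimingConfig = field(default_factory=OpticalTimingConfig)
    emitter: EmitterModel = field(default_factory=EmitterModel)
    sample: SampleConfig = field(default_factory=SampleConfig)
    link: LinkConfig = field(default_factory=LinkConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0
    out_dir: str = "."

    def resolved(self) -> dict[str, Any]:
        """Fully-resolved, serialisable copy (provenance block included)."""
        from . import __version__

        d = dataclasses.asdict(self)
        d["optical"]["image_dim_px"] = list(self.optical.image_dim_px)
        d["provenance"] = {"package": "sptcal", "version": __version__,
                           "seed": self.seed}
        return d


_SECTIONS = {
    "optical": OpticalTimingConfig,
    "emitter": EmitterModel,
    "sample": SampleConfig,
    "link": LinkConfig,
    "analysis": AnalysisConfig,
}


def _build_section(cls, values: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    for key in values:
        if key not in names:
            raise ConfigError(f"unknown key '{path}.{key}'")
    if cls is OpticalTimingConfig and "image_dim_px" in values:
        values = dict(values)
        values["image_dim_px"] = tuple(values["image_dim_px"])
    try:
        return cls(**values)
    except ConfigError as exc:
        raise ConfigError(f"in section '{path}': {exc}") from exc


def config_from_dict(data: dict[str, Any]) -> RunConfig:
    """Validate a nested dict (e.g. parsed YAML) into a :class:`RunConfig`.

    Unknown keys are rejected with their full path; missing keys take the
    apparatus defaults.
    """
    if not isinstance(data, dict):
        raise ConfigError("run configuration must be a mapping")
    data = dict(data)
    data.pop("provenance", None)
    kwargs: dict[str, Any] = {}
    for key, values in data.items():
        if key in _SECTIONS:
            if not isinstance(values, dict):
                raise ConfigError(f"section '{key}' must be a mapping")
            kwargs[key] = _build_section(_SECTIONS[key], values, key)
        elif key == "seed":
            kwargs["seed"] = int(values)
        elif key == "out_dir":
            kwargs["out_dir"] = str(values)
        else:
            raise ConfigError(f"unknown key '{key}'")
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    """Write the fully-resolved configuration (defaults applied) to YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.resolved(), fh, sort_keys=False)
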