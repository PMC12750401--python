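"""Registered deterministic fixtures used by the test-suite and examples.

``reference-bilayer`` is the reference condition of the calibration study:
D = 11 um^2 s^-1 at 0.035 particles um^-2 under the apparatus optics and
timing, with photobleaching and replenishment so the emitting density is
stationary.  ``dilute`` holds a single emitter (the tracking oracle) and
``fig4-cell`` is one cell of the accuracy grid (D = 1, 0.125 um^-2, no
bleaching).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

from .config import EmitterModel, OpticalTimingConfig, SampleConfig
from .simulate import (GroundTruth, ImageStack, PhotonTrace,
                       simulate_confocal_trace)
from .pipeline import simulate_stack

__all__ = ["make_fixture", "FIXTURES", "FixtureBundle"]


@dataclass
class FixtureBundle:
    name: str
    stack: ImageStack
    truth: GroundTruth
    trace: PhotonTrace | None
    sample: SampleConfig
    optical: OpticalTimingConfig
    emitter: EmitterModel


_REGISTRY: dict[str, dict] = {
    "reference-bilayer": dict(
        sample=dict(diffusion_um2_s=11.0, density_um2=0.035, replenish=True),
        optical=dict(n_frames=1000),
        # full EMCCD emulation: the apparatus runs its camera at high EM
        # gain, where gamma-distributed excess noise doubles the variance
        emitter=dict(em_excess_noise=True),
        confocal=True,
    ),
    "dilute": dict(
        sample=dict(diffusion_um2_s=11.0, density_um2=0.001, n_particles=1,
                    replenish=False),
        optical=dict(n_frames=200),
        emitter=dict(bleach_mean_photons=math.inf),
        confocal=False,
    ),
    "fig4-cell": dict(
        sample=dict(diffusion_um2_s=1.0, density_um2=0.125, replenish=False),
        optical=dict(n_frames=600),
        emitter=dict(bleach_mean_photons=math.inf),
        confocal=False,
    ),
}

FIXTURES = tuple(_REGISTRY)


def make_fixture(name: str, seed: int = 1,
                 n_frames: int | None = None,
                 confocal_duration_s: float = 20.0) -> FixtureBundle:
    """Build a registered fixture deterministically from (name, seed)."""
    if name not in _REGISTRY:
        raise KeyError(f"unknown fixture '{name}'; choose from {FIXTURES}")
    entry = _REGISTRY[name]
    optical_kwargs = dict(entry["optical"])
    if n_frames is not None:
        optical_kwargs["n_frames"] = n_frames
    optical = OpticalTimingConfig(**optical_kwargs)
    sample = SampleConfig(seed=seed, **entry["sample"])
    emitter = EmitterModel(**entry["emitter"])
    stack, truth = simulate_stack(sample, optical, emitter, seed=seed)
    trace = None
    if entry["confocal"]:
        trace = simulate_confocal_trace(sample, optical,
                                        duration_s=confocal_duration_s,
                                        seed=seed + 1)
    return FixtureBundle(name=name, stack=stack, truth=truth, trace=trace,
                         sample=sample, optical=optical, emitter=emitter)
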