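# Methods

`sptcal` implements, end to end, a dual-mode strategy for measuring lateral
diffusion of fluorescent lipids in planar (freestanding) bilayers: widefield
single-particle tracking (SPT) calibrated against confocal fluorescence
correlation spectroscopy (FCS).  The package contains a physics-level
simulator of both observation modes, a detector and linker, blur-corrected
diffusion estimators, the FCS analysis chain, and the two procedures that
select the linker's maximum linking radius (MLR).  Everything below is the
package's own account of the models and the choices made where the design
was genuinely open.

## The measurement problem

Frame-to-frame trajectory linking needs a maximum linking radius: the
largest displacement the linker will consider between consecutive frames.
Too small an MLR censors the long tail of genuine Brownian steps and
fragments trajectories, biasing the diffusion constant down; too large an
MLR admits false links between unrelated molecules, biasing it up — badly,
once the label density approaches experimentally useful values
(0.01–0.1 particles µm⁻²).  FCS measures `D` at a diffraction-limited spot
without any linking, so it provides an external standard: sweep the linker
over candidate MLRs, plot the centroid of the per-trajectory `log₁₀ D`
distribution against MLR, and take the MLR where the curve equals the FCS
value.  An internal-consistency diagnostic — the breakpoint ("kink") of the
semilogarithmic histogram of consecutive-frame squared displacements —
locates the same radius from tracking data alone.

## Simulator

**Trajectories.** 2D Brownian walks (per-axis Gaussian increments of
variance `2 D Δt`) on a periodic square domain whose side is the mask
diameter plus a 20 µm margin, so the emitting density inside the
illuminated disc is stationary.  Positions are stored unwrapped (clean
exposure averages and increments); the periodic boundary is applied at
emission time.  Initial positions are uniform; the particle count is
Poisson at `density × area` unless pinned.

**Widefield rendering.** Illumination is a hard-edged circularly masked 2D
Gaussian (mask diameter 37 µm ≈ 1100 µm², 1/e² beam radius set equal to
the mask diameter — the instrument's exact beam profile is not published,
so a gently falling profile, ≥ 0.6 relative intensity at the rim, was
chosen once).  Each frame exposes for 40 ms of a 42 ms interval; the
exposure is split into 10 substeps (convergence: doubling substeps changes
recovered `D` by < 2 %), each emitting Poisson photons at
`peak_rate × illumination`, placed at the emitter's substep position plus
Gaussian PSF scatter (the ~280 nm PSF radius is read as the 1/e² radius,
σ = 140 nm), and binned into 336 nm pixels.  Photobleaching caps each
molecule's cumulative emission with an exponential photon budget.  Camera
noise: Poisson signal and background, optional gamma-distributed EM excess
noise (variance ×2, the EMCCD at high gain), Gaussian read noise, gain
last.

**Photophysics defaults** (the dye's absolute photon numbers are not
published; chosen once as realistic for a cyanine lipid at ~120 W cm⁻²):
peak detected rate 5000 s⁻¹ (≈200 photons/frame at beam centre), photon
budget mean 6000 (bleach-limited median lifetime ≈ 20 frames), background
2 photons px⁻¹ frame⁻¹, read noise 1 count.  With replenishment enabled, a
bleached emitter is replaced by a fresh one spawned uniformly in the disc:
the physical membrane is ~16× the illuminated area and acts as an
unbleached reservoir, so the *observed* emitting density — the quantity
the experiment reports — stays stationary.  (Respawning outside the disc
was tried first and rejected: diffusion-limited resupply depressed the
observed density ~45 % below nominal.)

**Confocal mode.** Particles cross a Gaussian detection profile
`exp(−2r²/ω₁²)` with ω₁ = 312 nm; per 10 µs dwell bin the count is Poisson
at the summed intensity plus background (200 Hz default).  No bleaching
(negligible at FCS powers).  The amplitude convention is
`G(0) = 1/⟨N⟩` with `⟨N⟩ = density × π ω₁²`.

All randomness derives from one seed through `SeedSequence` spawning;
identical configuration + seed reproduces bit-identical stacks.

## Detection and linking

Detection per frame: difference-of-Gaussians bandpass, robust threshold
(median + k·1.4826·MAD, k = 5), local maxima, merge within a minimum
separation, then sub-pixel refinement by least-squares fitting of a
pixel-integrated 2D Gaussian (free position, amplitude, background and
width), run as a vectorised Gauss–Newton over all spots at once.  Two
choices matter and are worth stating plainly:

* **Blur-matched scale.** Motion during the 40 ms exposure widens spots by
  `sqrt(D·ΔT_exp/3)` per axis — at `D = 11 µm² s⁻¹` that is 1.1 px, triple
  the PSF σ.  `detect_params_for` sets the bandpass σ, merge separation
  and fit window from the expected spot size, using the FCS `D` (or the
  true `D` in simulation studies).  A fixed PSF-scale setting either
  over-merges slow dense fields or under-collects fast smeared spots.
* **Neighbour subtraction.** In crowded fields (≳0.05 µm⁻²) light from
  neighbours pulls single-spot fits by tens of nm per frame, inflating
  step SDs by up to ~25 %.  A second fit pass on windows with the fitted
  models of all other spots subtracted (multi-emitter refinement) removes
  most of the pull.
* **Photon floor at low blur.** Compact (slow-diffusion) emitters deliver
  ≥ 50 detected photons to the fit window even at the dim rim of the
  illumination, so dimmer detections there are noise or merge residue —
  and, if kept, they act as linker "detour points" that inflate
  long-trajectory estimates by 10–20 %.  A blur-dependent minimum
  intensity (50 photons at low blur, 30 at moderate, none at heavy blur,
  where genuine spots are spread thin) rejects them.

Localization uncertainty σ_loc is estimated either empirically (standard
deviation of repeated localizations of immobile emitters) or per spot from
photon statistics (Thompson-style `σ_a²/N·16/9` plus a background term);
pipelines use the median of the photon route per stack.

Linking: per consecutive frame pair, a linear assignment problem with
squared displacement as cost, links beyond the MLR forbidden, birth/death
cost `MLR²` (the standard convention; the tools this emulates publish no
auxiliary costs), solved globally per pair.  The time-based link range is
one frame — the bilayer dyes show no blinking — and no gap closing,
splitting or merging is attempted.  Intensity is excluded from the default
cost so the MLR remains the single calibrated control (a weighted variant
exists behind a flag).  Trajectories shorter than two points are dropped
with a count.

## Diffusion estimators

With static error σ_loc and a full-frame exposure, the observed MSD is

    MSD_obs(n) = 4 D (n Δt − ΔT_exp/3) + 4 σ_loc²

The single-step (SS) estimator inverts this at lag 1 on the trajectory's
mean squared displacement; the all-pairs (AP) estimator averages the
per-lag inversions up to `min(10, ⌈points/2⌉)` lags without regression.
Negative corrected values are kept in the per-trajectory table and
excluded, with a count, from log-space fitting.

The distribution of per-trajectory estimates is summarised by a Gaussian
fit to the histogram of `log₁₀ D` (0.1-decade bins, one count per
trajectory regardless of length).  The fit initialises at the histogram
mode and iteratively restricts itself to ±2.5 fitted widths around the
centre: linking errors contaminate the distribution with a heavy right
tail, and the quantity of interest is the central peak.  Fewer than 30
positive estimates, or a non-converging fit, falls back to the median of
`log₁₀ D` (flagged in the result).

Two biases of the SS centroid at the *optimal* MLR are understood and
deliberately not "corrected away": the MLR censors the upper ~1.5 % of
true steps at `D = 11`, worth about −6 % analytically, and short
bleach-limited trajectories add a small negative log-skew.  False links
push the other way; the net residual at the reference conditions is a few
per cent, which is why the crossing lands near, not exactly at, the
nominal radius.

## FCS chain

The multiple-tau correlator (16 lags per octave, successive binning by 2,
symmetric normalization) reproduces a hardware correlator in software; its
first octave equals direct correlation to machine precision (tested
against an O(N²) oracle).  The two-dimensional model
`G(τ) = (1/⟨N⟩)(1 + τ/τ_D)⁻¹` is fitted by least squares (weights when
curve uncertainties exist, else unweighted — the weighting convention is
not published); lags below 5 dwell times are excluded by default
(afterpulsing/shot-noise regime).  No triplet or photophysics terms.
`D = ω₁²/(4 τ_D)`.  A joint fit with shared τ_D across replicate curves
mirrors fitting curves collectively.

## MLR calibration

`mlr_sweep` links one detected spot table at every grid radius and fits
the logD_c centroid (detection runs once).  The crossing with the FCS
value interpolates a monotone (isotonic-regularised) version of the sweep,
because stochastic sweeps can be locally non-monotone; a sweep that does
not bracket the FCS value returns NaN with guidance to extend the grid.
Sweeps are replicated over ≥3 seeds; the crossing is computed on the mean
curve with spread from replicates.  A plateau-onset diagnostic (first MLR
within 0.05 decades of the sweep maximum) reproduces the failure mode of
plateau-based radius selection, which at these diffusion constants and
exposure times saturates only at radii several-fold beyond the optimum.

The kink diagnostic histograms lag-1 SDs from linking at the grid maximum
(0.25 µm² bins), fits `ln(counts)` with a continuous two-segment linear
model by breakpoint grid search (weights √count, since Var[ln n] ≈ 1/n for
Poisson counts), tests the two-segment model against a single line with an
F-test (α = 0.01; failure sets a no-kink flag instead of fabricating a
radius), and converts the SD breakpoint to an MLR by square root.  Whether
the histogram abscissa is SD (µm²) or displacement (µm) is ambiguous in
the field; both are implemented, SD is the default, and the choice is
recorded in the output.

## Accuracy grid

The grid study reproduces the expected-error analysis: ideal Brownian
motion without photobleaching, `D ∈ {1, 5, 11} µm² s⁻¹`, densities
0.001–0.125 µm⁻² (six log-spaced points by default), MLRs
{1.0, 2.3, 8.4, 15.1} µm, triplicate seeds, 800 frames per cell by
default.  Per cell: simulate → detect once → link per MLR → SS estimates
with blur + localization correction (σ_loc from the photon route) →
log-normal centroid → `100·(D_c − D_true)/D_true`.  Cells with too few
trajectories are marked invalid, not zero-filled.

The calibration fixture ("reference-bilayer": `D = 11`, 0.035 µm⁻², 1000
frames) differs from the grid in two respects, both deliberate: it keeps
photobleaching with replenishment, and it enables EM excess noise — it
replicates an *experimental* measurement on the real camera, whereas the
grid replicates a *simulation* study whose noise settings are not
published.

## What the simulations do and do not show

The generator emulates the stated apparatus faithfully at the level of
photon statistics, optics geometry, motion blur, bleaching and detector
noise.  It does not model bilayer curvature or 3D defocus, dye blinking
(none was observed in the system emulated), chip autofluorescence
structure (background is uniform), or hardware artefacts.  Passing tests
therefore demonstrate the correctness and calibration behaviour of the
algorithms under ideal planar imaging, not robustness to optical
aberrations of real chips.

## Numerical and scale choices

Desk-scale problem sizes are used throughout the validation suite: 60 s
confocal traces (6×10⁶ bins), calibration sweeps of 3 × 800–1000 frames
over a 13-point MLR grid, and a reduced 3×3×3-seed grid at 600–800
frames/cell.  Gauss–Newton spot fits run 15 damped iterations with
parameter clamps (position within the window, width 0.25–4 px); the LAP
uses a large-but-finite cost (10⁹) for forbidden links; scipy's
Hungarian solver makes tie-breaking deterministic.  Degenerate inputs
(empty frames, constant or saturated frames, zero-mean traces, sweeps
without a bracket, histograms without a kink) return flagged results or
raise with guidance rather than silently producing numbers.
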