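# sptcal

**FCS-calibrated single-particle tracking and diffusion measurement for
planar lipid bilayers.**

Single-particle tracking (SPT) in lipid bilayers reconstructs per-molecule
trajectories by detecting fluorescent spots in widefield movies and linking
them frame to frame.  Every practical linker needs a *maximum linking
radius* (MLR) — the largest displacement it will consider between
consecutive frames — and the measured diffusion constant depends on it
strongly: a too-small MLR censors genuine long Brownian steps (negative
bias), a too-large one admits false links between unrelated molecules
(positive bias, up to an order of magnitude at useful label densities).
`sptcal` implements a dual-mode calibration strategy for bilayers on
microelectrode cavity arrays and similar planar systems: fluorescence
correlation spectroscopy (FCS), which measures `D` at a confocal spot
without any linking, fixes the MLR for the tracking analysis.

The package provides:

* a **Brownian-motion microscopy simulator** replicating the apparatus
  (336 nm px⁻¹, 40 ms exposure / 42 ms interval, ~37 µm illuminated disc,
  280 nm-radius Gaussian PSF, confocal detection radius ω₁ = 312 nm,
  exponential photobleaching budgets, EMCCD noise), rendering both
  widefield image stacks and confocal photon traces;
* **spot detection** (DoG bandpass, robust threshold, vectorised
  pixel-integrated Gaussian fitting with neighbour subtraction) and
  **LAP linking** with a hard MLR and one-frame link range;
* **blur-corrected diffusion estimators** — single-step (SS) and all-pairs
  (AP), using `MSD_obs(n) = 4D(nΔt − ΔT_exp/3) + 4σ_loc²` — and the
  logarithmic-Gaussian centroid fit `logD_c` of per-trajectory estimates;
* the **FCS chain** — a multiple-tau correlator and weighted fits of
  `G(τ) = (1/⟨N⟩)(1 + τ/τ_D)⁻¹`, with `D = ω₁²/(4τ_D)`;
* two **MLR-selection procedures**: the crossing of the `logD_c(MLR)` sweep
  with the FCS diffusion constant, and the breakpoint ("kink") of the
  semilogarithmic histogram of consecutive-frame squared displacements;
* an **accuracy-grid study** quantifying the relative error of the
  centroid estimate versus true `D`, label density and MLR.

See `docs/methods.md` for the models, parameter conventions and
limitations.

## Worked example

Calibrate the MLR on a simulated reference bilayer (D = 11 µm² s⁻¹ at
0.035 particles µm⁻², the reference apparatus settings):

```python
import sptcal as sc
from sptcal.pipeline import detect_once, simulate_stack

# confocal mode: measure D by FCS
optical = sc.OpticalTimingConfig(n_frames=400)
sample = sc.SampleConfig(diffusion_um2_s=11.0, density_um2=0.035,
                         seed=2, replenish=True)
trace = sc.simulate_confocal_trace(sample, optical, duration_s=60.0, seed=2)
fcs = sc.fit_g2d(sc.autocorrelate(trace), omega1_nm=optical.omega1_nm)
print(f"FCS: D = {fcs.D_um2_s:.1f} um^2/s, tau_D = {fcs.tau_D_s*1e3:.2f} ms")

# widefield mode: track, sweep the MLR, calibrate
stack, _ = simulate_stack(sample, optical, sc.EmitterModel(em_excess_noise=True), seed=2)
spots, sigma_loc = detect_once(stack, d_hint_um2_s=fcs.D_um2_s)
timing = sc.TimingInfo.from_optical(optical)
result = sc.calibrate([spots], mlr_grid=[1.0, 1.4, 1.7, 2.0, 2.3, 2.6,
                                         3.0, 3.4, 4.2, 5.0, 5.9, 7.0, 8.4],
                      d_fcs_um2_s=fcs.D_um2_s, timing=timing,
                      sigma_locs=[sigma_loc])
print(f"crossing MLR = {result.crossing_mlr_um:.2f} um, "
      f"kink MLR = {result.kink_mlr_um:.2f} um, "
      f"plateau onset = {result.plateau_onset_mlr_um:.1f} um")
```

Output from this exact script (seed 2):

```
FCS: D = 9.9 um^2/s, tau_D = 2.46 ms
crossing MLR = 2.26 um, kink MLR = 2.26 um, plateau onset = 8.4 um
```

The two independent diagnostics agree: both the FCS crossing and the
squared-displacement kink put the optimal MLR at ~2.3 µm, far
below the ~8 µm where the sweep plateaus — selecting the radius by the
plateau would overestimate `D` several-fold at this density.  Linking at
the calibrated radius and fitting the per-trajectory distribution
(`sc.estimates_table` + `sc.fit_lognormal_centroid`) recovers a centroid
within a few per cent of the FCS value.

A command-line interface mirrors the library:

```bash
sptcal simulate --config run.yaml --out sim/
sptcal track    --stack sim/stack.tif --mlr 2.3 --out trk/
sptcal analyze  --tracks trk/tracks.csv --method ss --out ana/
sptcal fcs      --trace sim/trace.csv --omega1-nm 312 --out fcs/
sptcal calibrate --stack sim/stack.tif --d-fcs 11 --out cal/
sptcal error-grid --frames 800 --seed 1 --out grid/
```

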