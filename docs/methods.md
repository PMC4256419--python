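# Methods

## Forward model

One A-line is the sampled interferogram of a set of reflectors at depths
`z_r` (in air, single-sided from the zero-delay line):

    f(k_n) = Σ_r a_r · 10^(−ρ z_r / 20) · E(k_n) · cos(2 k_n z_r + φ_r + a₂ (k_n − k₀)²) + ε_n

* `k_n` — wavenumber samples, uniform in k (hardware k-clock emulation).
* `E(k)` — spectral amplitude envelope, Gaussian with FWHM 60.1 nm in
  wavelength by default (`envelope_shape="flat"` gives an idealized flat
  source, see *Exact-recovery configuration* below).
* `ρ` — sensitivity roll-off in dB/mm (default 5.7), modelled linear in dB
  versus depth because a single average decay slope characterizes the system.
* `a₂` — residual second-order dispersion (rad per (rad/µm)²; default 0).
  Only second order is modelled and compensated; higher orders are out of
  scope.
* `ε` — white Gaussian detector noise, calibrated so the reconstructed
  noise floor (rms bin magnitude) sits `noise_floor_db` below the
  reconstructed peak of a unit reflector at zero depth (default −100 dB,
  i.e. negligible).
* The per-A-line mean is subtracted, emulating balanced detection.

### Depth calibration and the k-grid

The reconstruction maps FFT bin `m` to depth `m·δz` with
`δz = depth_range / (n_k/2)`; defaults 5 mm / 512 px = 9.77 µm, matching the
system's quoted imaging geometry. This fixes the digitized k-span to
`π/δz ≈ 0.322 µm⁻¹`, an ≈ 88 nm window — narrower than the source's nominal
100 nm tuning range, as in real k-clocked systems where the digitizer window
covers only part of the sweep. The nominal sweep range is retained as
metadata and bounds the allowed envelope width.

### Doppler phase evolution and jitter

Between consecutive A-lines each moving voxel advances its phase by
`Δφ = 4π v Δt / λ₀` (positive v = motion toward the probe). The phase of
column `x` is the *exclusive* cumulative sum of these steps, so the measured
difference between columns `x` and `x+1` carries `v(x, z)` with no lateral
misalignment. Scan-phase jitter is modelled as independent N(0, σ²)
increments accumulated along the A-line index and common to all depths of an
A-line (trigger/scanner timing noise). With this convention the
inter-A-line phase difference on a static reflector has standard deviation
exactly σ — the quantity the phase-stability measurement reports (70 mrad
default) and the quantity that sets the minimum detectable velocity
`λ₀σ/(4πΔt)`. Had each A-line instead received an independent phase error,
differences would be √2 larger and the velocity noise floor inconsistent
with the phase-stability figure.

## Reconstruction

Per A-line: subtract the residual mean, apply the apodization window
(default Hann for sidelobe suppression; rect available for resolution
probing), multiply by `exp(−i a₂ᶜ (k−k₀)²)` for numerical dispersion
compensation, FFT, and keep the positive-depth half. `pad_factor` zero-pads
the FFT for sub-pixel PSF sampling. `to_db` uses
`20 log₁₀(|A| + ε)` with ε fixed at 10⁻¹² of full scale.

## Doppler processing

`phase_difference` computes `arg Σ_window A(x+1,·)·conj(A(x,·))` — the
adjacent-A-line Kasai autocorrelation, default window (1, 1) since the
instrument applies no averaging; wider windows trade resolution for phase
noise. The last column is an edge copy so the map keeps the image width.
`velocity_map` calibrates with `v = λ₀Δφ/(4πΔt)` (no refractive-index
factor by default, consistent with the in-air calibration; configurable),
gates validity where structural intensity is less than 10 dB above the
noise floor, and flags |Δφ| within 0.05 rad of π as wrapped. No unwrapping
is performed; velocities beyond ±λ₀/(4Δt) alias modulo 2·λ₀/(4Δt).

## Metrology design

* **Axial PSF.** FWHM of the linear-scale (magnitude) PSF via cubic-spline
  interpolation of the half-maximum crossings — mandatory because the
  9.77 µm pixel pitch is comparable to the ~12.6 µm PSF. For a Gaussian
  envelope of wavelength-FWHM Δλ the envelope-limited value is
  `(2 ln 2/π)·λ₀²/Δλ` (12.60 µm at 60.1 nm). The measurement uses a
  spectral window of 4× the envelope FWHM in k: on the default 88 nm
  imaging window the envelope is hard-truncated at ≈ 23% of peak, which
  convolves the PSF with a sinc and broadens the measured FWHM by ≈ 18%
  (≈ 10% even on the nominal 100 nm window). The wide-window experiment
  isolates the source-limited resolution, which is the figure the
  characterization report states; window-truncation broadening is a
  property of the imaging configuration, not of the source.
* **Roll-off.** Mirrors at 10 equally spaced depths over the imaging range;
  per depth the magnitude A-line is averaged over 32 noisy realizations
  (suppressing the single-draw bias of a −40 dB noise floor at the deepest
  mirrors), the zero-padded peak extracted in dB (8× padding removes
  scalloping), and the slope fitted by least squares. Exact on noise-free
  linear-in-dB input.
* **Phase stability.** Histogram of surface phase differences with
  Freedman–Diaconis bins, Gaussian fitted by least squares; the fitted sd is
  reported in mrad. 10⁴ A-lines give a sampling error well under the 5 mrad
  acceptance band.
* **Sensitivity.** `(peak − floor) + 2·ND` for a double-pass
  neutral-density filter; the simulated experiment places the configured
  noise floor at `−(budget + ρ·depth)` so the measured value equals the
  budget (the ND attenuation cancels by construction). Floor measured as
  rms magnitude over the signal-free deep half, consistent with the noise
  calibration.
* **Lateral resolution** is theory-only (`0.61·f·λ₀/D`); measuring it needs
  a physical USAF target.

## Phantom

Vessels are straight cylinders along the slow (Y) axis, so transverse
B-scans cut circular cross-sections — the geometry in which cross-sectional
patency analysis is done. `radius` is the inner-lumen radius (a 0.2585 mm
radius gives the 0.21 mm² reference cross-section); the wall is an annulus
outside it. Flow is Poiseuille, `v(r) = v_peak(1 − (r/R)²)`, zero outside
the flow region; "axial velocity" is the beam-parallel component with a
configurable cos θ Doppler-angle factor defaulting to 1. Thrombus is a
static, reflective angular sector of the lumen whose area fraction equals
`thrombus_fraction` exactly — the simplest geometry that reproduces partial
patency. Wall/blood/thrombus reflectivities are free parameters (defaults
0.5 / 0.2 / 0.6 against 0.05 background) since no tissue-contrast values
constrain them. Optional multiplicative speckle (unit-mean Rayleigh
amplitude + uniform static scatterer phase) is off by default.

What the phantom does *not* emulate: pulsatility, turbulence, vessel-wall
layering, lateral beam width (each A-line samples a single lateral column),
motion artifacts, and multiple scattering. Passing tests therefore validate
the processing chain and estimators, not in-vivo image quality.

## Exact-recovery configuration

With the Gaussian envelope the axial PSF spans ≈ 1.3 pixels, so
depth-adjacent voxels — whose accumulated Doppler phases diverge along the
fast axis — mix coherently and produce speckle-like Doppler noise of order
10% of v_peak in regions of velocity gradient. This is physically realistic
(it is why Kasai averaging exists) but masks estimator errors. End-to-end
parameter-recovery checks therefore use the leakage-free configuration:
flat spectral envelope, rect window, and the phantom depth grid aligned to
reconstruction bins (`z = i·δz`), in which each voxel maps to exactly one
FFT bin and recovery is exact to floating-point precision. The
Gaussian-envelope route is validated statistically (static-tissue velocity
noise, aliasing, centerline velocities).

## Scan waveforms

Fast axis per section: half-cosine lead-in
`f(t) = s·t − (A + sL)(1 − cos(πt/L))/2` over L samples (from rest 0 to the
ramp start −A, with `f′(0) = f′(L) = s`, the ramp slope `s = 2A/acq`),
linear ramp to +A over the acquisition points, then the time-reversed,
sign-flipped lead-out back to rest — every junction is continuous and
slope-continuous. The slow axis steps once per section; in C-scan mode the
first and last sections move the mirror to/from the park position and carry
no trigger (252 sections → 250 imaging frames; the plan type exposes both
counts since the hardware description is ambiguous on whether 250 or 252
frames image). B-scan mode holds Y at zero and triggers every section.
Triggers rise at the first acquisition sample. Amplitudes are normalized
(−1…1); physical voltage scaling belongs to the MEMS driver hardware.

## Quantification

Areas are pixel counts times pixel area (the ImageJ-style manual
measurement). Patency = 100·flow/lumen, narrowing = 100·(ref − area)/ref
(negative if dilated), thrombosis = 100 − patency; the identity
patency + thrombosis = 100 holds exactly before rounding. Percentages keep
one decimal internally and are rounded half-up to integers for display.
Flow masks come from Doppler-image segmentation by default; they may be
auto-derived as |v| ≥ v_min inside the lumen. Among the reference
measurements the worked examples draw on, one artery series (lumen areas
0.21 → 0.16 → 0.17 mm² quoted alongside narrowing of 23% and 16%) is
internally inconsistent — the area ratios give 23.8% and 19.0% — so the
tests pin the formula and the self-consistent examples (0.46 → 0.09 ⇒ 80%,
0.46 → 0.11 ⇒ 76%, 0.18 → 0.11 ⇒ 39%, 0.18 → 0.13 ⇒ 28%), not those two
quoted figures.

## Problem sizes and numerical choices

Unit and acceptance tests run reduced configurations chosen to keep the
physics identical: a 512-sample source over 2.5 mm preserves the default
9.77 µm pixel pitch; end-to-end scenes use ~300 × 256 B-scans; the
phase-stability experiment uses the full 10⁴ A-lines (a single-reflector
simulation is cheap); roll-off uses the full 10 depths over 5 mm.
Tie-breaks and degenerate inputs: empty masks yield area 0 with a warning;
constant phase inputs yield sd 0 with a warning; reflectors at negative or
out-of-range depths, vessels outside the grid, mismatched scene/source
geometry, and NaN fringes are rejected with diagnostics naming the
offending location.
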