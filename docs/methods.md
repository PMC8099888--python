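# Methods

## Signal model

Wide-field intensity at wavelength λ is modelled through a modified
Beer–Lambert budget. Relative attenuation against the pre-stimulus baseline,
ΔOD(λ,t) = −log₁₀(I(λ,t)/I_baseline(λ)), is decomposed as

    ΔOD(λ,t) = ε_HbO(λ) L(λ) ΔHbO(t) + ε_HbR(λ) L(λ) ΔHbR(t) − ΔS(t)

with two hemoglobin chromophores and one wavelength-independent tissue
light-scattering term. Three wavelengths (528 nm green, 625 nm red, 850 nm
near-infrared) make the system exactly determined; it is solved per time
point by a 3×3 linear solve with no regularization (the solve refuses tables
with condition number above 1e8).

**Sign conventions.** ΔS is carried in reflectance convention: an evoked
*darkening* of the cortex gives negative ΔS, while ΔHbO is positive and ΔHbR
negative during a response. The forward model converts exactly between the
fractional scattering change f and its attenuation equivalent,
ΔA = −log₁₀(1 + f), so the rendered evoked spot is dark (the observed
phenomenology), the unmixed LS trace is negative, and the signed correlation
between recovered HbO and LS amplitudes across a dose series is strongly
negative. Under the alternative convention (ΔS entering the OD budget with a
positive sign) the same pipeline would render a bright spot and flip that
correlation to +1; we consider the dark-spot/negative-LS convention the only
one consistent with both the imaging phenomenology and the reported negative
HbO–LS correlation.

**Pathlengths.** Differential pathlength factors L(λ) default to 1: no
absolute pathlength calibration is attempted, every downstream analysis is
normalized to its own control condition, and any fixed L(λ) cancels there.
They are configurable per wavelength for users with calibration data. The
shipped extinction table holds representative compiled hemoglobin molar
extinction magnitudes (green near-isosbestic; red HbR-dominated; NIR
HbO-dominated); any table can be loaded from CSV, and every validation path
is a forward/inverse round trip that is independent of the particular table.

## Synthetic forward model

The generator emulates the study conditions, not a particular animal:

* **Footprint** — a disk of exactly round(area/px²) pixels (rank-based, so the
  half-maximum mask hits the target area to within one pixel), default
  1.37 mm² on the 174×130 grid at 35 µm/px; a truncated-Gaussian footprint is
  available.
* **Kinetics** — each component follows 0 until onset, a half-cosine ramp over
  the rise time, then a single-exponential decay. Defaults: onset 0.8 s, rise
  2.4 s, decay 10.8 s, bracketing the reported neonatal OIS medians (onset
  0.6–1.1 s, rise 2.0–2.7 s, decay 10.5–11 s). The closed-form 10–90% rise
  time of the ramp is 0.5903 × rise. Hemodynamics lag the scattering component
  by a fixed 3 s neurovascular delay (the components are separated in time in
  neonates; no number is reported, so one is fixed and documented).
* **Amplitudes** — LS peak −0.002 *fractional* reflectance change (a 0.2% dark
  spot, matching reported amplitudes of 0.16–0.21%); ΔHbO +4e−8 and ΔHbR
  −1.6e−8 in pathlength-uncalibrated relative units (absolute hemodynamic
  magnitudes are not reported; only ratios matter downstream).
* **Dose scaling** — at concentration c all evoked amplitudes scale by
  exp(−c/τ); defaults τ = 1.4 g/kg (urethane) and 1.2% (isoflurane). HbO is
  linearly coupled to LS (fixed negative gain), baseline illumination and the
  footprint are concentration-independent.
* **Noise** — white Gaussian per pixel and frame, default SD 0.5% of baseline
  (a shot-noise-limited wide-field camera at a few 10⁴ effective
  photoelectrons per pixel), plus a multiplicative drift common to all pixels
  (linear trend + 30 s sinusoid, default amplitude 0.2%), which the
  reference-region correction removes exactly for spatially uniform baselines.
  All randomness flows through one seeded generator; truths are deterministic,
  so two seeds share ground truth and differ only in noise.

**What the generator does not emulate** — and hence what passing tests do not
establish about real data: photon-transport physics (Monte Carlo), vessel
anatomy and pulsation, heartbeat/respiration artifacts, motion, spatially
structured illumination, trial-to-trial kinetic variability, and any
anesthetic effect beyond pure amplitude scaling (e.g. dose-dependent kinetics
or area changes). Recovery results demonstrate the pipeline's correctness and
numerical behavior under the stated model, not robustness to those factors.

## Pipeline conventions and numerical choices

* **Referencing.** "First-frame subtraction" is generalized to the mean of all
  pre-stimulus baseline frames (a single frame is noise-dominated at 0.1–0.3%
  signals); the literal first-frame mode is available. The two agree exactly
  on drift-free input.
* **Inversion.** Reflection channels are multiplied by −1 in the OIS maps so
  an evoked darkening plots as a positive deflection; the transmission (IR)
  channel is kept as measured. Inversion is a visualization-layer convention
  only: decomposition always consumes non-inverted intensity ratios.
* **Illumination correction** subtracts the reference-region time profile
  (minus its mean) from every pixel; the default reference is the 10-px border
  ring, configurable, with a warning if it overlaps a known footprint.
* **Smoothing.** Spatial: per-frame 2D Gaussian, σ = 2 px, reflective
  boundaries. Temporal: unit-sum Kaiser windows (amplitude smoother 50 points,
  shape 2; contour-area smoother 12 points, shape 2 — the size is prescribed,
  the shape factor is matched to the amplitude smoother's). Smoothing is an
  explicit argument throughout: the reporting pipeline applies the 50-point
  window before peak picking, but recovery tests on noiseless data run
  unsmoothed, because an 8.3-s window at 6 Hz attenuates a ~3-s-wide peak by
  ~35% and stretches its apparent kinetics. Dose-response ratios are immune to
  this attenuation (it is amplitude-independent and cancels under control
  normalization).
* **Metric definitions.** Onset = first of ≥2 consecutive post-stimulus
  samples beyond baseline mean + 2 SD (interpolated to the crossing); rise =
  10→90% of peak; decay = peak→1/e; duration = time above 10% of peak. These
  operational rules are fixed here (the source parameters are named but not
  operationally defined) and are consistent with duration ≫ decay ≫ rise. The
  2·SD onset rule is threshold-relative: its expected value moves with the
  noise floor, so noisy-data checks compare against the rule applied to the
  clean waveform, not against the configured onset.
* **Contour detector.** Threshold = strict exceedance of the 95th (default;
  95–98 configurable) percentile of all finite pixels of the frame — constant
  frames yield empty sets. KDE: Gaussian kernel, Silverman bandwidth on the
  supra-threshold coordinates (overridable). "Half of the density" is read as
  0.5 × peak density; the contour is the connected half-maximum component
  containing the density maximum, falling back to the component containing
  the seed. The boundary polygon is traced on the raw density field at the
  half-maximum level (sub-pixel interpolation) and measured by the shoelace
  formula. Fullness = supra-threshold pixels inside the contour / pixels
  inside the contour. The percentile couples detector and geometry: the
  default 95 assumes the response occupies ≲5% of the field of view, which the
  130×174 acquisition grid satisfies for ~1.4 mm² responses. SNR quoted for
  detection tasks is amplitude / noise SD of the *trial-averaged* map; the
  σ=2 spatial filter belongs to the detector. A known limitation: when the
  per-frame noise is large enough that noise pixels claim a visible share of
  the top-5% slots even after spatial smoothing, the detected area erodes
  (measured ≈ −16% when the smoothed-map SNR itself is 5), because the
  percentile threshold rises above the footprint's half-maximum edge.
* **Exponential fits.** A(c) = a0·exp(−c/τ), a0, τ > 0, no additive offset
  (single concentration constants; an offset variant exists behind a flag for
  saturation analyses). Deterministic multi-start over a log-spaced τ grid,
  best sum of squares kept, ties broken toward smaller τ. Group τ = mean of
  per-series fits (not a pooled fit); CIs are 2.5 × leave-one-out jackknife SD
  (for the mean this equals 2.5·SD/√n exactly). r² is computed per series on
  normalized amplitudes. Per-10%-of-control increments step absolute levels
  (1.0→0.9→…), each step costing τ·ln(a/(a−0.1)); an exact ladder telescopes
  to τ·ln(high/low)/n_steps.
* **Containers.** Recordings are multi-page TIFF (written in the array's own
  dtype, so save→load round trips are bit-exact) plus a JSON sidecar holding
  the illumination schedule, stimulation protocol, pixel size, stimulus onsets
  and layout. Interleaving starts at channel 0; frame times are frame-center
  times from recording start; trailing incomplete rotations are dropped with a
  warning, never padded.

## Problem sizes

Validation and the acceptance script run at desk scale by design: full
174×130 grids, 4–12 trials per condition, 30 s inter-train intervals and
20–30 s post-stimulus windows. Because the whole measurement chain is linear
in the evoked amplitude and every dose curve is normalized to its own
control, these reductions change noise levels but not the recovered
constants. Amplitude-cohort analyses use 14 series per anesthetic with
multiplicative lognormal scatter (σ = 0.05); the coupling analysis renders
ROI-level three-wavelength traces for 14 animals × 10 concentrations with 1%
amplitude scatter applied before rendering (per-sample intensity noise at
that level would require a trial-averaging stage the trace-level analysis
does not include). The baseline-vs-concentration rank-correlation check uses
500 concentrations so the null Spearman SD (1/√(n−1) ≈ 0.045) sits well below
the 0.2 acceptance bound.

## Known limitations

* Absolute chromophore concentrations are not recoverable (unit pathlengths,
  relative extinction scale); only ratios and normalized dose curves are
  meaningful.
* The contour detector's percentile threshold ties detection to the expected
  footprint/field-of-view ratio and erodes areas at low map SNR (above).
* The dose model is a pure exponential with no floor; saturation behavior at
  high doses is outside the default model.
* The metric definitions (onset/rise/decay/duration) are this package's
  operational choices; other reasonable rules would shift absolute values
  while preserving orderings.
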