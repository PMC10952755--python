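# Methods

This note records the physical model, the numerical choices, and the
limitations of the package, in the spirit of a simulator's model
documentation.

## Bloch simulation of slice-selective excitation

Excitation is simulated in the hard-pulse approximation: the RF waveform is
discretized into short rectangular sub-pulses (512 samples over the 3.2 ms
window by default; convergence-tested), and at every through-slice position
z the magnetization is rotated about the instantaneous effective field
(RF amplitude/phase plus local off-resonance).  All fields are expressed as
precession frequencies — RF amplitude as nutation frequency in Hz,
off-resonance in Hz, gradients in kHz/cm — so no gyromagnetic ratio appears.
Relaxation during the pulse is neglected; post-excitation the state evolves
by (a) the slice-refocusing lobe, modeled as an instantaneous phase ramp of
half the slice-select moment (the off-resonance precession during the lobe
is folded into the free-precession interval), (b) free precession
`exp(-i 2π B0(z) t_free)`, and (c) T2 decay and T1 recovery.

**Sign conventions.** Transverse phase evolves as `exp(-i 2π f t)` for
positive off-resonance f.  The slice-select gradient is stored as a positive
magnitude with a polarity field, and the **default polarity is negative**,
matching the vendor 2D GRE-EPI excitation this package models.  The
polarity matters: it fixes whether a negative through-slice B0 gradient
reinforces or cancels the residual phase roll left by half-moment
refocusing.  With negative polarity, a −45 Hz/cm gradient reinforces the
dephasing at 130° (peak-to-peak phase split ≈ 0.92π at TE, near-complete
destructive interference), lowers the DAM ratio, and makes the
slice-profile-only B1+ estimate *over*-shoot — which is the behavior that
produces under-estimated T1 at the liver dome.

**TE referencing.** The echo time runs on the simulation clock that starts
at the beginning of the RF window: the explicit free-precession time after
the pulse is `TE − duration`.  Together with the off-resonance precession
that the Bloch simulation itself accrues during the pulse, this convention
reproduces the quantitative phase-split and error-scaling behavior of the
modeled sequence; referencing TE to the pulse center instead shifts the
phase split by ~0.09π and steepens the error-scaling slope by ~20%.

**Through-slice grid.** Profiles are sampled on ±0.5 cm with 201 points.
The excited slice (8 mm nominal, 2.54 kHz/cm gradient, time-bandwidth ≈ 6.7)
is fully contained in this window.  The window size is not innocuous: the
ambiguity angle of the ratio curve depends on how much of the low-signal
profile tail is integrated (±0.5 cm gives ≈ 95.8°; ±1 cm gives ≈ 91°), and
the constant-offset invariance of the ratio (a constant B0 shifts the
excited slice by off/G ≈ 0.02 cm/50 Hz) holds to 1e-6 only when the window
also covers the shifted profile — with a ±1 cm window the invariance is
< 1e-6, with the tight default window truncation limits it to ~7e-4 at
50 Hz.  Both facts are verified in tests and stable under grid refinement.
Doubling the grid from 201 to 401 points changes the ratio by < 0.1% for
flips of 5°–160°.

## The excitation pulse

The vendor's GRE-EPI excitation is modeled as a symmetric Hamming-windowed
sinc parameterized by its time-bandwidth product, which is found by
bisection so that the amplitude main lobe has the published FWHM (0.55 ms
within a 3.2 ms window; that pins TBW ≈ 6.7, consistent with the 8 mm slice
at 2.54 kHz/cm).  The amplitude scale is calibrated so the on-resonance
hard-pulse flip (360° × Σ amplitude·dt) equals the nominal flip.  The exact
vendor waveform (side-lobe truncation, apodization coefficients) is not
public; pulse-shape-dependent quantities (ambiguity angle, error-scaling
slope) therefore carry a few-percent model uncertainty.

## The DAM ratio LUT and its inversion

The on-resonance ratio `R(α) = |∫Mxy(2α)|/|∫Mxy(α)|` is tabulated at 1°
steps (1°–160° by default, so the double angle reaches 320°), including the
refocusing ramp and propagation to TE (uniform T2 decay cancels in the
ratio; it is kept for fidelity and provenance).  R is strictly decreasing up
to the ambiguity angle — the argmin of the table, refined by local quadratic
interpolation — and inversion is linear interpolation of flip angle versus
ratio on that monotone branch.  Out-of-range ratios clip to the branch
endpoints with a logged warning; NaN ratios map to missing voxels.  The
65°/130° pair sits comfortably below the ≈ 96° ambiguity angle for B1+
factors up to ~1.45.

## Through-slice B0 model and per-voxel correction

The multi-slice field map (1 cm slice pitch: 8 mm slices, 2 mm gap) is
interpolated per in-plane pixel with a cubic spline (not-a-knot end
conditions, so linear/quadratic/cubic fields are reproduced exactly).
Pixels with fewer than four valid slices fall back to the highest feasible
polynomial order and are flagged; fewer than two are excluded and counted.
Beyond the sampled slice range the end cubic is continued rather than
clamped: the edge slices need the field half a slice beyond the last
center, and a constant clamp zeroes the local gradient exactly at the dome
slice, where the correction matters most (with clamping the noiseless
phantom retained a ~50 ms spurious corrected ΔT1; with cubic continuation
residuals vanish).  Extrapolated support is still flagged per voxel, since
real extrapolated field maps are less trustworthy than this smooth phantom.

Per masked voxel the B1+ factor is the bounded ([0.1, 2.0]) scalar
least-squares match of the acquired ratio to the Bloch-simulated ratio with
the voxel's spline-evaluated B0 profile (evaluated directly on the Bloch z
grid), started from the slice-profile-only LUT estimate.  Two solver paths
give identical results: a per-voxel scipy `least_squares` reference and a
damped, bounded secant iteration vectorized over all voxels of a slice,
which evaluates the Bloch simulator for the whole batch per iteration
(typically 4–5 evaluations).  Convergence: squared residual < 1e-10 or step
< 1e-6; non-converged voxels return their best iterate, flagged.

## SPGR signal model and T1 fitting

The ideal spoiled steady state is the Ernst equation.  Incomplete spoiling
is modeled with extended phase graphs: per TR an RF rotation with the
quadratic phase schedule φ_k = k(k+1)/2 × increment mixes the F+/F−/Z
configuration ladders, relaxation acts over TR, and the gradient spoiler
shifts transverse orders by one.  The RF spoiling increment is **not**
published for the modeled sequence; the default is 50° (vendor-typical),
configurable.  Orders are truncated at 150, where per-TR T2 decay
(T2/TR = 30/4.1 ms) makes higher orders negligible (< 1e-9 relative).  The
recursion stops when the geometrically extrapolated remaining transient —
not the raw TR-to-TR change, which underestimates the residual for slowly
converging small flips — falls below 1e-6 of the signal, requiring three
consecutive passes to avoid early oscillatory false positives; the cap is
4000 TRs with a warning.  The EPG implementation agrees with an independent
uniformly-dephased isochromat-ensemble simulation to better than 1e-4
(machine precision at matched TR counts).

For fitting, the EPG/Ernst ratio is tabulated over flip angle (0.1–40°,
0.25° steps) and T1 (10–5000 ms, geometric spacing) and evaluated
bilinearly (< 0.1% off-grid error, tested at ~1e-5); queries outside the
grid clamp with a warning.  Per voxel the true flips are the B1+ factor
(trilinearly resampled to the SPGR grid if needed) times the nominal flips;
M0 enters linearly and is profiled out, leaving a bounded 1-D minimization
in T1 (bounds 10–5000 ms) initialized from the linearized two-point DESPOT1
slope.  All four volumes (2°, 2°, 15°, 15°) enter as independent
observations.  T2 is fixed at 30 ms for the spoiling correction, not
fitted.

The through-slice trend is an OLS fit of ROI-mean T1 versus slice index
(circular ROIs, three per slice by default); ΔT1 = slope × number of
slices, with a 95% CI from the slope's standard error.  The cross-subject
mixed model that would consume these per-subject tables is out of scope;
the tables it needs are emitted.

## The synthetic phantom

`generate_phantom` produces a 32×32×15 grid by default (0.7 cm in-plane
pixels, 1 cm slice pitch) with:

- an elliptical organ mask;
- a smooth in-plane B1+ field spanning [0.59, 1.14] — the liver range at 3T;
- T1/T2/M0 uniform at 900 ms / 30 ms / 1;
- a dome-like B0 field `amp · m(x,y) · exp(-(z_dome - z)/decay)` with
  amp = 200 Hz at the dome (the last slice center, i.e. slice index
  increases toward the lung interface), in-plane modulation m ∈ [0.35, 1]
  (a seeded smooth bump), and the decay length chosen analytically so the
  maximum finite-difference through-slice slope at 1 cm pitch is 45 Hz/cm.

The through-slice gradients achieved are therefore single-polarity
(≈ 0.5–45 Hz/cm), as at a real dome; the full ±45 Hz/cm range of gradients
is exercised by the linear-gradient simulation sweeps rather than by the
phantom.  This choice is deliberate: a field with both polarities inside
one organ makes the per-method median B1+ errors and the ROI slice trend
partially cancel, destroying exactly the two downstream signatures the
phantom exists to demonstrate (error ordering naive > slice-profile >
corrected, all with the same sign; and a large single-signed uncorrected
ΔT1).

Forward simulation: the DAM pair is Bloch-simulated per masked voxel with
the voxel's continuous true B0 profile and true B1+ (TR 10 s — fully
relaxed); the B0 map samples the true field at slice centers plus Gaussian
noise; SPGR volumes use the exact EPG signal at the true flips (the 3D SPGR
excitation is nonselective, so no slice-profile effects there).  Noise is
Rician (complex Gaussian before magnitude), default SNR 50 referenced to
the mean α-image signal.  Identical seed and config give bit-identical
phantoms and noise.

What the phantom does **not** emulate: EPI geometric distortion (assumed
corrected upstream), fat compartments and fat saturation, respiratory
motion, anatomically realistic organ shape, in-plane B0 gradients (only the
slice direction is modeled, as in the correction itself).  Passing tests
therefore demonstrate the correctness of the correction machinery under its
own physical model, not robustness to those real-world effects.

## Problem sizes used by the test suite

The full pipeline is exercised at reduced sizes chosen for the package's
test turnaround: 10–16 pixel in-plane grids (15 slices always), a 51-point
Bloch grid and 256 pulse samples for the replicate study, and ROI-restricted
T1 fitting when only the slice trend is consumed.  The replicate study runs
20 seeded phantoms with realistic noise (DAM and SPGR at SNR 50, 1 Hz B0
noise) and checks that |ΔT1| shrinks after correction in ≥ 95% of them.
Headline simulation quantities (error-scaling slope, phase split, ambiguity
angle) always use the full 201-point/512-sample geometry.

## Numerical tolerances worth knowing

- Norm conservation of the rotation kernel: |M| = 1 to 1e-9.
- Small-tip excitation agrees with the pulse's Fourier transform to < 1%.
- Inverse-crime B1+ recovery (data generated by the same simulator):
  < 5e-3 absolute in the B1+ factor; batch and scipy solvers agree to
  ~1e-5 (their shared stopping tolerance).
- Noiseless T1 round trip through the EPG model: < 0.5% bias.
- T1 RMSE under SNR-50 Rician noise is ≈ 3.2% for the 2°/2°/15°/15°
  protocol at TR 4.1 ms — that is the protocol's information content, not a
  solver limitation (least squares is ML-efficient at this noise level).

## Known limitations

- The pulse is a reconstruction from two published descriptors; absolute
  pulse-shape-dependent numbers inherit that uncertainty.
- The RF spoiling increment default (50°) is an assumption; T1 accuracy
  statements are made against the same configured model.
- B0 spline extrapolation beyond the imaged stack is flagged but not
  penalized; real field maps degrade faster than the smooth phantom.
- Only through-slice B0 variation is corrected; strong in-plane gradients
  within a voxel are outside the model.
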