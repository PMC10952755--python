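# b1dam

Double-angle B1+ mapping for 2D gradient-echo acquisitions, with correction
for slice-profile effects and for B0 gradients along the slice direction,
plus the downstream variable-flip-angle (VFA) SPGR T1 mapping that consumes
the corrected B1+ map.  Everything is validated on a synthetic digital liver
phantom with known ground truth.

## Who this is for

Quantitative-MRI researchers who calibrate transmit (B1+) fields with the
double-angle method (DAM) on multi-slice gradient-echo (GRE/GRE-EPI)
sequences — e.g., for liver T1 mapping at 3T — and need accurate B1+ near
organs with strong susceptibility gradients (the liver dome under the lung).

## The problem and the model

The DAM estimates the true flip angle from two fully-relaxed GRE signals at
nominal flips 2α and α:

    α(r) = arccos( S₂(r) / 2 S₁(r) ),      B1⁺ = α_true / α_nominal

Two confounders invalidate this on 2D multi-slice data:

1. **Slice profile.** A selective pulse does not produce a rectangular flip
   profile, and beyond the small-tip regime the half-moment refocusing lobe
   leaves a residual phase roll across the slice.  The measured ratio of
   slice-integrated complex signals,

       R(α) = | ∫ Mxy(z; 2α) dz | / | ∫ Mxy(z; α) dz |,

   differs from 2cos α.  `build_ratio_lut` Bloch-simulates R(α) for the
   actual pulse and inverts it by interpolation on its monotone branch,
   below the *ambiguity angle* where R reaches its minimum.

2. **Through-slice B0 gradients (∇zB0).** A B0 gradient along z adds to or
   cancels the slice-select dephasing, changing the two integrals
   differently and biasing the ratio.  `DoubleAngleModel.fit("b0_corrected")`
   solves, per voxel,

       argmin_{B1⁺} ( R_acq − R_sim[ B0(z), G_ss, G_ref, RF, TE ] )²,

   where B0(z) comes from a per-pixel cubic spline through the multi-slice
   field map and R_sim is the same Bloch simulation with that off-resonance
   profile.

The corrected B1+ map then scales the nominal flips of a VFA SPGR
acquisition (2°, 2°, 15°, 15°; TR 4.1 ms); `VFAT1Model.fit` performs a
voxelwise NLLS of the Ernst steady state with an extended-phase-graph (EPG)
incomplete-spoiling correction, and `T1MapResult.slice_trend` quantifies
the residual through-slice T1 gradient (ΔT1 = slope × number of slices).

## Worked example

```python
import numpy as np
from b1dam import make_hws_pulse, SliceSelection, build_ratio_lut, TissueParams
from b1dam.pipeline import RunConfig, run_pipeline

# the liver protocol: 3.2 ms Hamming-windowed sinc (FWHM 0.55 ms),
# 2.54 kHz/cm slice-select gradient, 8 mm slice, TE 11 ms
pulse = make_hws_pulse(duration=3.2, fwhm_target=0.55, n_samples=512)
geom = SliceSelection(gradient=2.54)
lut = build_ratio_lut(pulse, geom, te=11.0, tissue=TissueParams())
print(f"ambiguity angle: {lut.ambiguity_angle:.1f} deg")
i65 = np.argwhere(lut.fa_grid == 65.0)[0][0]
print(f"ratio at 65 deg: {lut.ratios[i65]:.4f}  (ideal 2 cos 65 = {2*np.cos(np.radians(65)):.4f})")

# full pipeline on a noiseless 16x16x15 phantom with a dome-like B0 field
cfg = RunConfig(phantom={"nx": 16, "ny": 16}, seed=0,
                dam_noise_sigma=0.0, spgr_noise_sigma=0.0, b0_noise_hz=0.0)
report = run_pipeline(cfg)
print(report["b1_error_table"].round(3).to_string(index=False))
print(report["delta_t1_table"].round(1).to_string(index=False))
```

prints

```
ambiguity angle: 95.8 deg
ratio at 65 deg: 0.8964  (ideal 2 cos 65 = 0.8452)
       method  median_err_pct  iqr_low  iqr_high  rmse_pct
        naive          -3.770   -6.089    -2.780     5.744
slice_profile          -1.631   -4.212    -0.634     4.324
 b0_corrected          -0.000   -0.000     0.000     0.011
    b1_method  mean_t1_ms  delta_t1_ms  ci_low  ci_high
slice_profile       960.8        201.0   137.4    264.7
 b0_corrected       900.0          0.3    -0.1      0.6
```

Reading this: the slice profile raises the on-resonance 65° ratio from
0.845 to 0.896 and pushes the invertibility limit from 90° to ~96°.  On the
phantom (true T1 = 900 ms everywhere, B0 rising to ~200 Hz at the dome),
the naive arccos inversion is biased by −3.8% (median), slice-profile
correction alone still carries the ∇zB0 bias (−1.6% median, and a spurious
201 ms T1 gradient across the 15 slices), while the full correction
recovers B1+ to 0.01% RMSE and flattens the T1 trend to 0.3 ms.

## Command line

`b1dam` exposes the same pipeline as subcommands operating on NIfTI
volumes and CSV tables: `make-phantom`, `build-lut`, `correct-b1`,
`fit-t1`, `analyze-trend`, `run-all` (see `b1dam --help`).

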