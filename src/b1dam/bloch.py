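"""Hard-pulse Bloch simulation of slice-selective excitation.

Each through-slice position evolves independently: per RF time sample the
magnetization is rotated about the instantaneous effective-field axis set by
the RF amplitude/phase and the local off-resonance (static B0 offset plus
slice-select gradient field), all expressed as precession frequencies in Hz.
Relaxation during the pulse is neglected.  After excitation the refocusing
lobe is applied as an instantaneous phase ramp and the state is propagated
to the echo time with free precession and T1/T2 relaxation.

Conventions: positions in cm, times in ms, frequencies in Hz, gradients in
kHz/cm.  Free precession at frequency f evolves the transverse magnetization
as exp(-i*2*pi*f*t); no gyromagnetic constant appears (fields are
pre-expressed as frequencies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pulses import RFPulse

__all__ = [
    "SliceSelection", "OffResonanceProfile", "MagnetizationProfile",
    "TissueParams", "AcquisitionParams",
    "simulate_excitation", "excite_profiles", "propagate_to_te",
    "integrate_slice",
]


@dataclass(frozen=True)
class SliceSelection:
    """Slice-selection geometry.

    ``gradient`` is the slice-select amplitude during RF as a positive
    magnitude in kHz/cm; ``polarity`` gives its sign (the vendor GRE-EPI
    excitation plays the slice-select gradient with negative polarity, which
    sets the sense in which a through-slice B0 gradient reinforces or cancels
    the slice-select dephasing).  ``refocus_fraction`` is the refocusing-lobe
    moment as a fraction of the slice-select moment.  ``z_grid`` is the
    through-slice position grid (cm) profiles are evaluated on.
    """

    gradient: float                      # kHz/cm during RF, magnitude
    slice_thickness: float = 8.0         # mm
    refocus_fraction: float = 0.5
    polarity: float = -1.0
    z_grid: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.gradient <= 0:
            raise ValueError("gradient must be positive (use polarity for its sign)")
        if self.polarity not in (-1.0, 1.0, -1, 1):
            raise ValueError("polarity must be +1 or -1")
        if not (0 < self.refocus_fraction <= 1):
            raise ValueError("refocus_fraction must lie in (0, 1]")
        z = self.z_grid
        if z is None:
            z = default_z_grid()
        z = np.asarray(z, dtype=float)
        if z.ndim != 1 or z.size < 3 or np.any(np.diff(z) <= 0):
            raise ValueError("z_grid must be strictly increasing with >= 3 points")
        object.__setattr__(self, "z_grid", z)

    @property
    def signed_gradient_hz_per_cm(self) -> float:
        return float(self.polarity) * self.gradient * 1e3


def default_z_grid(extent_cm: float = 0.5, n_points: int = 201) -> np.ndarray:
    """Symmetric through-slice grid, +/- ``extent_cm`` about slice center.

    The default (+/-0.5 cm, 201 points) covers the full extent of the
    excited slice profile for the 8 mm slice / 2.54 kHz/cm geometry."""
    return np.linspace(-extent_cm, extent_cm, n_points)


@dataclass(frozen=True)
class OffResonanceProfile:
    """B0 offset along the slice direction, as precession frequency (Hz)."""

    z_positions: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self):
        z = np.asarray(self.z_positions, dtype=float)
        f = np.asarray(self.frequencies, dtype=float)
        if z.shape != f.shape:
            raise ValueError("z_positions and frequencies must have equal shape")
        if not np.all(np.isfinite(f)):
            raise ValueError("off-resonance values must be finite")
        object.__setattr__(self, "z_positions", z)
        object.__setattr__(self, "frequencies", f)

    @classmethod
    def on_resonance(cls, z: np.ndarray) -> "OffResonanceProfile":
        z = np.asarray(z, float)
        return cls(z, np.zeros_like(z))

    @classmethod
    def linear(cls, z: np.ndarray, slope_hz_per_cm: float,
               offset_hz: float = 0.0) -> "OffResonanceProfile":
        z = np.asarray(z, float)
        return cls(z, offset_hz + slope_hz_per_cm * z)


@dataclass(frozen=True)
class TissueParams:
    """Relaxation parameters: T1, T2 in ms and equilibrium magnetization."""

    t1: float = 900.0
    t2: float = 30.0
    m0: float = 1.0

    def __post_init__(self):
        if not (self.t1 >= self.t2 > 0):
            raise ValueError("require t1 >= t2 > 0")
        if self.m0 <= 0:
            raise ValueError("m0 must be positive")


@dataclass(frozen=True)
class AcquisitionParams:
    """DAM acquisition timing and flip-angle pair."""

    te: float = 11.0                 # ms
    tr: float = 10000.0              # ms
    nominal_fa_pair: tuple = (65.0, 130.0)
    n_slices: int = 15
    slice_thickness: float = 8.0     # mm
    slice_gap: float = 2.0           # mm

    def __post_init__(self):
        a, b = self.nominal_fa_pair
        if b != 2 * a:
            raise ValueError("DAM pair must satisfy 2*alpha = double angle exactly")
        if not self.te < self.tr:
            raise ValueError("require te < tr")

    @property
    def slice_pitch_cm(self) -> float:
        return (self.slice_thickness + self.slice_gap) / 10.0


@dataclass
class MagnetizationProfile:
    """Complex transverse (Mxy) and longitudinal (Mz) magnetization on a
    through-slice position grid, for unit initial magnetization."""

    z_positions: np.ndarray
    transverse: np.ndarray
    longitudinal: np.ndarray

    def magnitude(self) -> np.ndarray:
        return np.abs(self.transverse)

    def phase(self) -> np.ndarray:
        return np.angle(self.transverse)


def _rotate_hard_pulse_numpy(fx_seq, fy_seq, dt_s, fz, scale):
    """Sequential hard-pulse rotations (vectorized numpy path).

    fx_seq, fy_seq : (n_t,) RF nutation frequency components, Hz
    fz : (n,) local precession frequency per case, Hz
    scale : (n,) per-case RF amplitude scale
    Returns (mx, my, mz) arrays of shape (n,), starting from (0, 0, 1).
    """
    shape = fz.shape
    mx = np.zeros(shape)
    my = np.zeros(shape)
    mz = np.ones(shape)
    two_pi = 2.0 * np.pi
    for fx0, fy0 in zip(fx_seq, fy_seq):
        fx = fx0 * scale
        fy = fy0 * scale
        f = np.sqrt(fx * fx + fy * fy + fz * fz)
        # rotation angle about the effective-field axis (precession sense:
        # positive fz advances Mxy phase as exp(-i 2 pi f t))
        phi = -two_pi * f * dt_s
        with np.errstate(invalid="ignore", divide="ignore"):
            ux = np.where(f > 0, fx / f, 0.0)
            uy = np.where(f > 0, fy / f, 0.0)
            uz = np.where(f > 0, fz / f, 1.0)
        c = np.cos(phi)
        s = np.sin(phi)
        dot = ux * mx + uy * my + uz * mz
        cx = uy * mz - uz * my
        cy = uz * mx - ux * mz
        cz = ux * my - uy * mx
        k = dot * (1.0 - c)
        mx = mx * c + cx * s + ux * k
        my = my * c + cy * s + uy * k
        mz = mz * c + cz * s + uz * k
    return mx, my, mz


try:  # optional numba acceleration of the inner rotation loop
    from numba import njit as _njit

    @_njit(cache=True)
    def _rotate_kernel(fx_seq, fy_seq, dt_s, fz, scale):  # pragma: no cover
        n = fz.size
        out = np.empty((3, n))
        two_pi = 2.0 * np.pi
        for i in range(n):
            mx = 0.0
            my = 0.0
            mz = 1.0
            fzi = fz[i]
            sc = scale[i]
            for t in range(fx_seq.size):
                fx = fx_seq[t] * sc
                fy = fy_seq[t] * sc
                f = np.sqrt(fx * fx + fy * fy + fzi * fzi)
                if f > 0.0:
                    ux = fx / f
                    uy = fy / f
                    uz = fzi / f
                    phi = -two_pi * f * dt_s
                    c = np.cos(phi)
                    s = np.sin(phi)
                    dot = ux * mx + uy * my + uz * mz
                    cx = uy * mz - uz * my
                    cy = uz * mx - ux * mz
                    cz = ux * my - uy * mx
                    k = dot * (1.0 - c)
                    mx = mx * c + cx * s + ux * k
                    my = my * c + cy * s + uy * k
                    mz = mz * c + cz * s + uz * k
            out[0, i] = mx
            out[1, i] = my
            out[2, i] = mz
        return out

    def _rotate_hard_pulse(fx_seq, fy_seq, dt_s, fz, scale):
        flat_fz = np.ascontiguousarray(fz.ravel())
        flat_sc = np.ascontiguousarray(np.broadcast_to(scale, fz.shape).ravel())
        out = _rotate_kernel(np.ascontiguousarray(fx_seq),
                             np.ascontiguousarray(fy_seq),
                             dt_s, flat_fz, flat_sc)
        return (out[0].reshape(fz.shape), out[1].reshape(fz.shape),
                out[2].reshape(fz.shape))

except Exception:  # pragma: no cover - numba absent
    def _rotate_hard_pulse(fx_seq, fy_seq, dt_s, fz, scale):
        return _rotate_hard_pulse_numpy(fx_seq, fy_seq, dt_s, fz,
                                        np.broadcast_to(scale, fz.shape))


def excite_profiles(pulse: RFPulse, slice_sel: SliceSelection,
                    offres_freqs: np.ndarray, flip_angles: np.ndarray):
    """Batched excitation: simulate post-pulse magnetization for several
    on-resonance-calibrated flip angles and off-resonance profiles at once.

    Parameters
    ----------
    offres_freqs : (..., n_z) or (n_z,) off-resonance in Hz on the z grid.
    flip_angles : (...,) on-resonance hard-pulse flip angles in degrees
        (already including any B1+ factor).  Broadcast against the leading
        dims of ``offres_freqs``.

    Returns
    -------
    mxy : complex ndarray, shape broadcast(...) + (n_z,)
    mz : real ndarray, same shape
    """
    z = slice_sel.z_grid
    offres_freqs = np.atleast_1d(np.asarray(offres_freqs, float))
    flip_angles = np.asarray(flip_angles, float)
    if offres_freqs.shape[-1] != z.size:
        raise ValueError("off-resonance profile length does not match z grid")
    fz_local = offres_freqs + slice_sel.signed_gradient_hz_per_cm * z

    scales = flip_angles / pulse.nominal_flip
    scales_b = np.asarray(scales)[..., None]
    out_shape = np.broadcast_shapes(scales_b.shape, fz_local.shape)
    fz_full = np.ascontiguousarray(np.broadcast_to(fz_local, out_shape), dtype=float)
    scl_full = np.broadcast_to(scales_b, out_shape)

    fx_seq = pulse.amplitudes * np.cos(pulse.phases)
    fy_seq = pulse.amplitudes * np.sin(pulse.phases)
    mx, my, mz = _rotate_hard_pulse(fx_seq, fy_seq, pulse.time_step * 1e-3,
                                    fz_full, scl_full)
    return mx + 1j * my, mz


def simulate_excitation(pulse: RFPulse, slice_sel: SliceSelection,
                        offres: OffResonanceProfile, b1_factor: float,
                        fa_nominal: float) -> MagnetizationProfile:
    """Simulate slice-selective excitation of unit equilibrium magnetization.

    The pulse amplitude is scaled so the on-resonance hard-pulse flip equals
    ``b1_factor * fa_nominal``; returns the state immediately after the pulse
    (before the refocusing lobe)."""
    z = slice_sel.z_grid
    if offres.z_positions.shape != z.shape or not np.allclose(offres.z_positions, z):
        raise ValueError("off-resonance profile is not defined on the slice z grid")
    mxy, mz = excite_profiles(pulse, slice_sel, offres.frequencies,
                              np.asarray(b1_factor * fa_nominal))
    return MagnetizationProfile(z, mxy, mz)


def propagate_to_te(profile: MagnetizationProfile, slice_sel: SliceSelection,
                    offres: OffResonanceProfile, te: float,
                    pulse_duration: float,
                    tissue: TissueParams | None = None) -> MagnetizationProfile:
    """Apply the slice-refocusing lobe and free precession to the echo time.

    The refocusing lobe is modeled as an instantaneous phase ramp of
    ``refocus_fraction * gradient * pulse_duration * z`` with sign opposite
    to the slice-select accrual.  TE runs on the simulation clock that starts
    at the beginning of the RF window, so the post-pulse free-precession time
    is ``te - pulse_duration``; it carries precession at the local
    off-resonance and, when ``tissue`` is given, T2 decay and T1 recovery
    toward ``m0``.
    """
    t_free_ms = te - pulse_duration
    if t_free_ms <= 0:
        raise ValueError("te must exceed the pulse duration (TE referenced to pulse start)")
    z = profile.z_positions
    ramp = (2.0 * np.pi * slice_sel.refocus_fraction
            * slice_sel.signed_gradient_hz_per_cm * z * pulse_duration * 1e-3)
    t_free_s = t_free_ms * 1e-3
    phase = ramp - 2.0 * np.pi * offres.frequencies * t_free_s
    mxy = profile.transverse * np.exp(1j * phase)
    mz = profile.longitudinal
    if tissue is not None:
        mxy = mxy * np.exp(-t_free_ms / tissue.t2)
        e1 = np.exp(-t_free_ms / tissue.t1)
        mz = tissue.m0 + (mz - tissue.m0) * e1
    return MagnetizationProfile(z, mxy, mz)


def integrate_slice(profile: MagnetizationProfile) -> complex:
    """Trapezoidal integral of the complex transverse magnetization over z."""
    z = np.asarray(profile.z_positions, float)
    if z.ndim != 1 or z.size < 3:
        raise ValueError("need at least 3 grid points")
    if np.any(np.diff(z) <= 0):
        raise ValueError("z grid must be strictly increasing")
    return complex(np.trapezoid(profile.transverse, z, axis=-1))


def integrate_profiles(mxy: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Trapezoidal z-integral for batched profiles (last axis = z)."""
    return np.trapezoid(mxy, np.asarray(z, float), axis=-1)
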