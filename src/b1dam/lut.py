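"""Double-angle method (DAM) signal-ratio lookup table.

The naive DAM inverts arccos(S2/(2 S1)) per voxel, which assumes an ideal
rectangular slice profile.  For a real slice-selective pulse the measured
ratio of slice-integrated complex signals at flip angles 2*alpha and alpha
differs from 2*cos(alpha): the ratio-vs-flip-angle curve is tabulated by
Bloch simulation (on resonance) and inverted by linear interpolation on its
monotone branch below the ambiguity angle, where the curve reaches its
minimum and stops being invertible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bloch import (SliceSelection, TissueParams, excite_profiles,
                    integrate_profiles)
from .pulses import RFPulse

__all__ = ["RatioLUT", "dam_naive_fa", "build_ratio_lut", "invert_lut",
           "rectangular_ratio_lut"]

logger = logging.getLogger(__name__)

MISSING = np.nan


def dam_naive_fa(s1, s2):
    """Naive double-angle flip angle: arccos(s2 / (2 s1)), degrees.

    Arguments may be scalars or arrays; ``s1`` must be positive.  Arguments
    with s2/(2 s1) above 1 are clipped to 1 (returning 0 deg) with a logged
    warning, matching the degenerate-input policy for noisy magnitudes.
    """
    s1 = np.asarray(s1, float)
    s2 = np.asarray(s2, float)
    if np.any(s1 <= 0):
        raise ValueError("s1 must be positive")
    x = s2 / (2.0 * s1)
    n_clip = int(np.sum(x > 1.0))
    if n_clip:
        logger.warning("dam_naive_fa: clipped %d ratio(s) above 1 to 1", n_clip)
    x = np.clip(x, -1.0, 1.0)
    out = np.degrees(np.arccos(x))
    return float(out) if out.ndim == 0 else out


@dataclass
class RatioLUT:
    """On-resonance DAM ratio |S(2a)|/|S(a)| versus flip angle a.

    ``ambiguity_angle`` is the flip angle minimizing the ratio; the LUT is
    invertible only on [fa_grid[0], ambiguity_angle].
    """

    fa_grid: np.ndarray          # degrees
    ratios: np.ndarray
    ambiguity_angle: float       # degrees
    context: dict = field(default_factory=dict)

    def __post_init__(self):
        self.fa_grid = np.asarray(self.fa_grid, float)
        self.ratios = np.asarray(self.ratios, float)

    @property
    def monotone_branch(self):
        """(fa, ratio) arrays of the strictly decreasing invertible branch."""
        i_min = int(np.argmin(self.ratios))
        return self.fa_grid[: i_min + 1], self.ratios[: i_min + 1]

    def to_csv(self, path, provenance_path=None):
        pd.DataFrame({"fa_deg": self.fa_grid, "ratio": self.ratios}).to_csv(
            path, index=False)
        if provenance_path is not None:
            import yaml
            with open(provenance_path, "w") as fh:
                yaml.safe_dump({"ambiguity_angle_deg": float(self.ambiguity_angle),
                                **self.context}, fh)

    @classmethod
    def from_csv(cls, path, provenance_path=None):
        df = pd.read_csv(path)
        ctx = {}
        if provenance_path is not None:
            import yaml
            with open(provenance_path) as fh:
                ctx = yaml.safe_load(fh)
        fa = df["fa_deg"].to_numpy()
        r = df["ratio"].to_numpy()
        amb = ctx.pop("ambiguity_angle_deg", None)
        if amb is None:
            amb = _refine_argmin(fa, r)
        return cls(fa, r, float(amb), ctx)


def _refine_argmin(fa: np.ndarray, r: np.ndarray) -> float:
    """Grid argmin refined by local quadratic interpolation."""
    i = int(np.argmin(r))
    if 0 < i < r.size - 1:
        y0, y1, y2 = r[i - 1], r[i], r[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom > 0:
            delta = 0.5 * (y0 - y2) / denom
            step = fa[i + 1] - fa[i]
            return float(fa[i] + delta * step)
    return float(fa[i])


def simulate_integrated_signals(pulse: RFPulse, slice_sel: SliceSelection,
                                te: float, tissue: TissueParams,
                                flip_angles: np.ndarray,
                                offres_freqs=None) -> np.ndarray:
    """|integrated complex signal| at TE for each requested flip angle.

    ``offres_freqs`` defaults to on-resonance; it may be (n_z,) shared by all
    flips or (n_fa, n_z).  Includes the refocusing-lobe phase ramp, free
    precession and T2 decay to TE (uniform decay cancels in any ratio but is
    kept for fidelity).
    """
    z = slice_sel.z_grid
    if offres_freqs is None:
        offres_freqs = np.zeros_like(z)
    offres_freqs = np.asarray(offres_freqs, float)
    flip_angles = np.atleast_1d(np.asarray(flip_angles, float))
    mxy, _ = excite_profiles(pulse, slice_sel, offres_freqs, flip_angles)
    duration = pulse.duration
    t_free_ms = te - duration
    if t_free_ms <= 0:
        raise ValueError("te must exceed the pulse duration")
    ramp = (2.0 * np.pi * slice_sel.refocus_fraction
            * slice_sel.signed_gradient_hz_per_cm * z * duration * 1e-3)
    phase = ramp - 2.0 * np.pi * offres_freqs * (t_free_ms * 1e-3)
    mxy = mxy * np.exp(1j * phase) * np.exp(-t_free_ms / tissue.t2)
    return np.abs(integrate_profiles(mxy, z))


def build_ratio_lut(pulse: RFPulse, slice_sel: SliceSelection, te: float = 11.0,
                    tissue: TissueParams = TissueParams(),
                    fa_grid: np.ndarray | None = None) -> RatioLUT:
    """Tabulate the on-resonance DAM ratio |S(2a)|/|S(a)| over ``fa_grid``.

    Default grid is 1..160 degrees in 1 degree steps (the double angle then
    reaches 320 degrees).  Flip angles whose denominator integral magnitude
    falls below 1e-12 are flagged invalid (NaN ratio).
    """
    if fa_grid is None:
        fa_grid = np.arange(1.0, 161.0, 1.0)
    fa_grid = np.asarray(fa_grid, float)
    if np.any(fa_grid <= 0) or np.any(fa_grid > 360) or np.any(np.diff(fa_grid) <= 0):
        raise ValueError("fa_grid must be monotone within (0, 360]")
    all_fas = np.concatenate([fa_grid, 2.0 * fa_grid])
    uniq, inv = np.unique(all_fas, return_inverse=True)
    sig_u = simulate_integrated_signals(pulse, slice_sel, te, tissue, uniq)
    sig = sig_u[inv]
    s1 = sig[: fa_grid.size]
    s2 = sig[fa_grid.size:]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where(s1 > 1e-12, s2 / s1, np.nan)
    n_bad = int(np.sum(~np.isfinite(ratios)))
    if n_bad:
        logger.warning("build_ratio_lut: %d flip angle(s) flagged invalid", n_bad)
    amb = _refine_argmin(fa_grid[np.isfinite(ratios)], ratios[np.isfinite(ratios)])
    ctx = {"pulse": dict(pulse.meta, nominal_flip=pulse.nominal_flip,
                         n_samples=pulse.n_samples),
           "gradient_khz_per_cm": slice_sel.gradient,
           "refocus_fraction": slice_sel.refocus_fraction,
           "slice_thickness_mm": slice_sel.slice_thickness,
           "n_z": int(slice_sel.z_grid.size),
           "z_extent_cm": float(slice_sel.z_grid[-1]),
           "te_ms": te, "t1_ms": tissue.t1, "t2_ms": tissue.t2}
    return RatioLUT(fa_grid, ratios, amb, ctx)


def rectangular_ratio_lut(fa_grid: np.ndarray | None = None) -> RatioLUT:
    """Ideal rectangular-profile LUT: ratio = |sin 2a|/|sin a| = 2|cos a|."""
    if fa_grid is None:
        fa_grid = np.arange(1.0, 161.0, 1.0)
    fa_grid = np.asarray(fa_grid, float)
    ratios = 2.0 * np.abs(np.cos(np.radians(fa_grid)))
    amb = _refine_argmin(fa_grid, ratios)
    return RatioLUT(fa_grid, ratios, amb, {"pulse": {"shape": "rectangular-profile"}})


def invert_lut(lut: RatioLUT, ratio_acq, warn: bool = True):
    """Invert acquired DAM ratio(s) to flip angle (degrees) on the monotone
    branch below the ambiguity angle.  Out-of-range ratios clip to the branch
    endpoints with a logged warning; NaN ratios map to NaN.
    """
    fa_b, r_b = lut.monotone_branch
    good = np.isfinite(r_b)
    fa_b, r_b = fa_b[good], r_b[good]
    ratio_acq = np.asarray(ratio_acq, float)
    scalar = ratio_acq.ndim == 0
    r = np.atleast_1d(ratio_acq)
    # ratio decreasing in fa: interpolate fa as function of ratio (ascending)
    r_asc = r_b[::-1]
    fa_asc = fa_b[::-1]
    out = np.full(r.shape, MISSING)
    finite = np.isfinite(r)
    n_out = int(np.sum((r[finite] > r_asc[-1]) | (r[finite] < r_asc[0])))
    if n_out and warn:
        logger.warning("invert_lut: %d ratio(s) outside the invertible branch "
                       "[%g, %g]; clipped", n_out, r_asc[0], r_asc[-1])
    out[finite] = np.interp(r[finite], r_asc, fa_asc)
    return float(out[0]) if scalar else out
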