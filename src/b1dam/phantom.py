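"""Synthetic digital phantom and forward simulators.

The phantom emulates a 2D multi-slice liver protocol: 15 slices of 8 mm
thickness with 2 mm gap (1 cm pitch), a smooth in-plane B1+ factor field
spanning the liver range seen at 3T, and a dome-like B0 field that is
largest at the first slice (near the lung interface) and decays with
distance, producing through-slice gradients up to ~45 Hz/cm in magnitude.
T1/T2 default to liver-like 900/30 ms.  Forward simulators produce the DAM
magnitude pair (full-relaxation GRE at 65/130 deg), a multi-slice B0 map,
and multi-flip-angle SPGR volumes (EPG signal model; the 3D SPGR excitation
is nonselective so no slice-profile effects are modeled there), each with
optional Rician noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .bloch import SliceSelection, TissueParams, AcquisitionParams
from .epg import SPGRAcquisition, epg_spoiled_signal_batch
from .lut import simulate_integrated_signals
from .pulses import RFPulse

__all__ = ["PhantomConfig", "SyntheticPhantom", "generate_phantom",
           "forward_dam", "forward_spgr", "sample_b0_map"]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, field and noise configuration of the synthetic phantom."""

    nx: int = 32
    ny: int = 32
    n_slices: int = 15
    pixel_size_cm: float = 0.7
    slice_thickness_mm: float = 8.0
    slice_gap_mm: float = 2.0
    b0_amplitude_hz: float = 200.0       # dome B0 offset at the first slice
    b0_max_slope_hz_per_cm: float = 45.0  # target max |through-slice slope|
    b1_range: tuple = (0.59, 1.14)
    t1_ms: float = 900.0
    t2_ms: float = 30.0
    m0: float = 1.0
    snr: float = 50.0                    # at the alpha DAM image
    b0_noise_hz: float = 1.0
    mask_semiaxes: tuple = (0.42, 0.42)  # as fraction of nx, ny

    @property
    def slice_pitch_cm(self) -> float:
        return (self.slice_thickness_mm + self.slice_gap_mm) / 10.0

    @property
    def b0_decay_cm(self) -> float:
        """Through-slice decay length giving the target finite-difference
        slope between the two slice centers nearest the dome."""
        amp = self.b0_amplitude_hz
        target = self.b0_max_slope_hz_per_cm * self.slice_pitch_cm
        if amp == 0 and target == 0:
            return 1.0   # field identically zero; decay length irrelevant
        if not (0 < target < amp):
            raise ValueError(
                "requested slope range is infeasible for the configured B0 "
                f"amplitude: need 0 < {target} < {amp}")
        return -self.slice_pitch_cm / np.log1p(-target / amp)


@dataclass
class SyntheticPhantom:
    """Ground-truth fields on the acquisition grid plus the continuous B0
    generator used by the forward simulators."""

    config: PhantomConfig
    seed: int
    b1_true: np.ndarray          # (nx, ny, n_slices)
    t1_true: np.ndarray
    t2_true: np.ndarray
    m0: np.ndarray
    mask: np.ndarray             # boolean (nx, ny, n_slices)
    b0_inplane: np.ndarray = field(repr=False, default=None)  # (nx, ny) modulation

    @property
    def slice_centers_cm(self) -> np.ndarray:
        return np.arange(self.config.n_slices) * self.config.slice_pitch_cm

    @property
    def dome_z_cm(self) -> float:
        """Position of the susceptibility dome: the last slice center
        (slice index increases toward the lung interface)."""
        return (self.config.n_slices - 1) * self.config.slice_pitch_cm

    def b0_at(self, ix, iy, z_cm):
        """Continuous ground-truth B0 (Hz) at in-plane pixel(s) and
        through-slice position(s).  The offset grows exponentially toward
        the dome (the last slice center, adjacent to the lung interface)
        and decays with distance from it, giving a positive through-slice
        gradient everywhere; the field is smooth in z."""
        m = self.b0_inplane[ix, iy]
        d = self.dome_z_cm - np.asarray(z_cm, float)
        decay = np.exp(-d / self.config.b0_decay_cm)
        return self.config.b0_amplitude_hz * np.asarray(m)[..., None] * decay

    def b0_true_at_centers(self) -> np.ndarray:
        """Noise-free B0 sampled at the slice centers, (nx, ny, n_slices)."""
        zc = self.slice_centers_cm
        decay = np.exp(-(self.dome_z_cm - zc) / self.config.b0_decay_cm)
        return (self.config.b0_amplitude_hz * self.b0_inplane[:, :, None]
                * decay[None, None, :])

    def manifest(self) -> dict:
        return {"config": asdict(self.config), "seed": self.seed}


def generate_phantom(config: PhantomConfig = PhantomConfig(), seed: int = 0
                     ) -> SyntheticPhantom:
    """Deterministically generate the phantom for a config and seed."""
    cfg = config
    _ = cfg.b0_decay_cm  # validates slope feasibility
    rng = np.random.default_rng(seed)
    nx, ny, ns = cfg.nx, cfg.ny, cfg.n_slices
    x = np.arange(nx)[:, None]
    y = np.arange(ny)[None, :]
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0

    # elliptical organ mask, identical across slices
    ax, ay = cfg.mask_semiaxes[0] * nx, cfg.mask_semiaxes[1] * ny
    mask2d = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0
    mask = np.repeat(mask2d[:, :, None], ns, axis=2)

    # dome-like in-plane B0 modulation: a smooth positive bump (peak
    # jittered by seed) rescaled over the mask to [0.35, 1], so every
    # in-plane pixel shares the dome polarity while the gradient magnitude
    # varies substantially across the organ
    jx = cx + rng.uniform(-0.1, 0.1) * nx
    jy = cy + rng.uniform(-0.1, 0.1) * ny
    sig = 0.3 * max(nx, ny)
    bump = np.exp(-(((x - jx) ** 2 + (y - jy) ** 2) / (2 * sig ** 2)))
    bmin, bmax = bump[mask2d].min(), bump[mask2d].max()
    b0_inplane = 0.35 + 0.65 * (bump - bmin) / (bmax - bmin)

    # smooth low-order B1+ field spanning the configured range exactly
    phi = rng.uniform(0, 2 * np.pi)
    u = (x - cx) / nx
    v = (y - cy) / ny
    s = np.sin(2 * np.pi * (0.35 * u + 0.25 * v) + phi) + 0.35 * np.cos(
        2 * np.pi * (0.2 * u - 0.3 * v))
    s = (s - s[mask2d].min()) / (s[mask2d].max() - s[mask2d].min())
    lo, hi = cfg.b1_range
    b1_2d = np.clip(lo + (hi - lo) * s, lo, hi)
    b1_true = np.repeat(b1_2d[:, :, None], ns, axis=2)

    shape = (nx, ny, ns)
    return SyntheticPhantom(
        config=cfg, seed=seed, b1_true=b1_true,
        t1_true=np.full(shape, cfg.t1_ms), t2_true=np.full(shape, cfg.t2_ms),
        m0=np.full(shape, cfg.m0), mask=mask, b0_inplane=b0_inplane)


def _rician(mag: np.ndarray, sigma: float, rng) -> np.ndarray:
    if sigma <= 0:
        return mag
    re = mag + rng.normal(0.0, sigma, mag.shape)
    im = rng.normal(0.0, sigma, mag.shape)
    return np.hypot(re, im)


def forward_dam(phantom: SyntheticPhantom, acq: AcquisitionParams,
                pulse: RFPulse, slice_sel: SliceSelection,
                noise_sigma: float | None = None, seed: int = 0):
    """Forward-simulate the DAM magnitude pair (alpha, 2*alpha).

    Each masked voxel's slice-integrated complex signal is Bloch-simulated
    with its own through-slice B0 profile (from the continuous ground-truth
    field) and its true B1+ factor; TR is long enough for full relaxation.
    ``noise_sigma=None`` sets the Rician sigma from the configured SNR at
    the alpha image; pass 0 for noiseless.
    """
    if noise_sigma is not None and noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    cfg = phantom.config
    tissue = TissueParams(t1=cfg.t1_ms, t2=cfg.t2_ms, m0=cfg.m0)
    fa1, fa2 = acq.nominal_fa_pair
    z = slice_sel.z_grid
    zc = phantom.slice_centers_cm

    ii, jj, ss = np.nonzero(phantom.mask)
    b1 = phantom.b1_true[ii, jj, ss]
    off = phantom.b0_at(ii, jj, zc[ss][:, None] + z[None, :])
    flips = np.concatenate([b1 * fa1, b1 * fa2])
    offs = np.concatenate([off, off], axis=0)
    m0v = phantom.m0[ii, jj, ss]
    sig = simulate_integrated_signals(pulse, slice_sel, acq.te, tissue,
                                      flips, offs) * np.concatenate([m0v, m0v])
    n = b1.size
    s1, s2 = sig[:n], sig[n:]

    img1 = np.zeros(phantom.mask.shape)
    img2 = np.zeros(phantom.mask.shape)
    img1[ii, jj, ss] = s1
    img2[ii, jj, ss] = s2
    if noise_sigma is None:
        noise_sigma = float(np.mean(s1)) / cfg.snr
    rng = np.random.default_rng(seed)
    img1 = _rician(img1, noise_sigma, rng)
    img2 = _rician(img2, noise_sigma, rng)
    return img1, img2


def sample_b0_map(phantom: SyntheticPhantom, noise_sigma_hz: float = 0.0,
                  seed: int = 0) -> np.ndarray:
    """Multi-slice B0 field map: ground truth at slice centers + Gaussian
    noise, over the whole in-plane FOV."""
    if noise_sigma_hz < 0:
        raise ValueError("noise must be >= 0 Hz")
    b0 = phantom.b0_true_at_centers()
    if noise_sigma_hz > 0:
        rng = np.random.default_rng(seed)
        b0 = b0 + rng.normal(0.0, noise_sigma_hz, b0.shape)
    return b0


def forward_spgr(phantom: SyntheticPhantom, acq: SPGRAcquisition,
                 noise_sigma: float | None = None, seed: int = 0,
                 restrict_mask: np.ndarray | None = None) -> np.ndarray:
    """Forward-simulate SPGR magnitude volumes at each nominal flip angle.

    Per masked voxel the steady-state EPG signal at the true flip angle
    (b1_true * nominal) is computed; slice-profile effects are not modeled
    (nonselective 3D excitation).  Returns (nx, ny, n_slices, n_fa).
    ``restrict_mask`` limits simulation to a sub-mask (e.g. ROI voxels).
    """
    if noise_sigma is not None and noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    cfg = phantom.config
    mask = phantom.mask if restrict_mask is None else (phantom.mask & restrict_mask)
    ii, jj, ss = np.nonzero(mask)
    b1 = phantom.b1_true[ii, jj, ss]
    t1 = phantom.t1_true[ii, jj, ss]
    t2 = phantom.t2_true[ii, jj, ss]
    m0 = phantom.m0[ii, jj, ss]
    fas = np.asarray(acq.nominal_fas, float)
    out = np.zeros(mask.shape + (fas.size,))
    ref_sig = None
    for k, fa in enumerate(fas):
        if fa == 0:
            continue
        sig = epg_spoiled_signal_batch(b1 * fa, t1, t2, acq.tr,
                                       acq.rf_phase_increment) * m0
        out[ii, jj, ss, k] = sig
        if fa == np.max(fas):
            ref_sig = sig
    if noise_sigma is None:
        noise_sigma = (float(np.mean(ref_sig)) / cfg.snr) if ref_sig is not None else 0.0
    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        for k in range(fas.size):
            out[..., k] = _rician(out[..., k], noise_sigma, rng)
    return out
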