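"""Steady-state SPGR signal models: ideal Ernst equation and extended
phase graphs (EPG) with quadratic RF spoiling.

The ideal spoiled gradient-echo steady state is the Ernst equation
``m0 sin(a) (1-E1)/(1-E1 cos(a))``.  Real sequences spoil imperfectly: the
EPG recursion tracks transverse/longitudinal configuration states under the
quadratic RF phase schedule phi_k = k (k+1)/2 * increment, with relaxation
over each TR and a unit gradient-spoiler shift of transverse state orders.
The incomplete-spoiling correction is the ratio of the EPG steady-state
signal to the Ernst value, tabulated over (flip angle, T1) and evaluated by
bilinear interpolation at fit time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

logger = logging.getLogger(__name__)

__all__ = ["SPGRAcquisition", "spgr_ideal_signal", "epg_spoiled_signal",
           "epg_spoiled_signal_batch", "SpoilingCorrection",
           "spoiling_correction"]


@dataclass(frozen=True)
class SPGRAcquisition:
    """SPGR acquisition: TR (ms), nominal flip angles (deg), TE (ms, T2*
    neglected in the signal model), quadratic RF-spoiling phase increment
    (deg) and spoiler gradient moment (dephasing cycles per voxel per TR)."""

    tr: float = 4.1
    nominal_fas: tuple = (2.0, 2.0, 15.0, 15.0)
    te: float = 1.23
    rf_phase_increment: float = 50.0
    spoiler_cycles_per_tr: float = 1.0

    def __post_init__(self):
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if len(set(self.nominal_fas)) < 2:
            raise ValueError("need >= 2 distinct flip angles")
        if not (0 <= self.rf_phase_increment < 360):
            raise ValueError("rf_phase_increment must lie in [0, 360)")


def spgr_ideal_signal(t1, m0, fa, tr):
    """Ernst steady-state SPGR signal; fa in degrees, t1/tr in ms."""
    t1 = np.asarray(t1, float)
    fa = np.asarray(fa, float)
    if np.any(t1 <= 0):
        raise ValueError("t1 must be positive")
    if np.any((fa <= 0) | (fa >= 180)):
        raise ValueError("fa must lie in (0, 180)")
    e1 = np.exp(-tr / t1)
    a = np.radians(fa)
    return m0 * np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a))


def _epg_case_numpy(fa_deg, t1, t2, tr, inc_deg, n_tr, K, tol):
    """One EPG case; returns (signal, converged, achieved remaining)."""
    fp = np.zeros(K, complex)    # F+ states, order 0..K-1
    fm = np.zeros(K, complex)    # F- states
    zs = np.zeros(K, complex)
    zs[0] = 1.0
    e1 = np.exp(-tr / t1)
    e2 = np.exp(-tr / t2)
    a = np.radians(fa_deg)
    ca2 = np.cos(a / 2) ** 2
    sa2 = np.sin(a / 2) ** 2
    sa = np.sin(a)
    ca = np.cos(a)
    inc = np.radians(inc_deg)
    sig_prev = 0.0
    change_prev = np.inf
    remaining = np.inf
    streak = 0
    for k_tr in range(n_tr):
        phi = 0.5 * k_tr * (k_tr + 1) * inc
        eip = np.exp(1j * phi)
        eim = np.conj(eip)
        e2ip = eip * eip
        e2im = eim * eim
        fp_n = ca2 * fp + sa2 * e2ip * fm - 1j * eip * sa * zs
        fm_n = sa2 * e2im * fp + ca2 * fm + 1j * eim * sa * zs
        zs_n = -0.5j * eim * sa * fp + 0.5j * eip * sa * fm + ca * zs
        # signal: demodulated F0 immediately after the RF pulse
        sig = float(np.abs(fp_n[0]))
        if k_tr >= 2:
            change = abs(sig - sig_prev)
            # geometric extrapolation of the remaining transient; require a
            # run of consecutive passes so early oscillatory near-zero
            # changes do not trigger a premature exit
            passed = False
            if change < change_prev:
                denom = change_prev - change
                remaining = (change * change / denom if denom > 0 else 0.0)
                passed = remaining < tol * max(sig, 1e-30)
            streak = streak + 1 if passed else 0
            if streak >= 3 and k_tr >= 20:
                return sig, True, remaining / max(sig, 1e-30)
            change_prev = change
        elif k_tr == 1:
            change_prev = abs(sig - sig_prev)
        sig_prev = sig
        # relaxation over TR then gradient spoiler shift of transverse orders
        fp_n *= e2
        fm_n *= e2
        zs_n *= e1
        zs_n[0] += 1.0 - e1
        fp[1:] = fp_n[:-1]
        fm[:-1] = fm_n[1:]
        fm[-1] = 0.0
        # the order shift moves the old F-(order -1) population into order 0,
        # where it reappears as conj in the F+ ladder
        fp[0] = np.conj(fm_n[1])
        zs = zs_n
    return sig_prev, False, remaining / max(sig_prev, 1e-30)


def _epg_batch_numpy(fa_deg, t1, t2, tr, inc_deg, n_tr, n_states, tol):
    n = fa_deg.size
    sig = np.empty(n)
    conv = True
    ach = 0.0
    for i in range(n):
        s, c, a = _epg_case_numpy(fa_deg[i], t1[i], t2[i], tr, inc_deg,
                                  n_tr, n_states, tol)
        sig[i] = s
        conv = conv and c
        ach = max(ach, a)
    return sig, conv, ach


try:  # optional numba acceleration
    from numba import njit as _njit

    @_njit(cache=True)
    def _epg_batch_kernel(fa_deg, t1, t2, tr, inc_deg, n_tr, K, tol):  # pragma: no cover
        n = fa_deg.size
        sig_out = np.empty(n)
        conv = np.ones(n, np.bool_)
        ach = np.zeros(n)
        inc = np.radians(inc_deg)
        for i in range(n):
            fp = np.zeros(K, np.complex128)
            fm = np.zeros(K, np.complex128)
            zs = np.zeros(K, np.complex128)
            zs[0] = 1.0
            e1 = np.exp(-tr / t1[i])
            e2 = np.exp(-tr / t2[i])
            a = np.radians(fa_deg[i])
            ca2 = np.cos(a / 2) ** 2
            sa2 = np.sin(a / 2) ** 2
            sa = np.sin(a)
            ca = np.cos(a)
            sig_prev = 0.0
            change_prev = 1e300
            remaining = 1e300
            streak = 0
            done = False
            for k_tr in range(n_tr):
                phi = 0.5 * k_tr * (k_tr + 1) * inc
                eip = np.exp(1j * phi)
                eim = np.conj(eip)
                e2ip = eip * eip
                e2im = eim * eim
                fp_n = ca2 * fp + sa2 * e2ip * fm - 1j * eip * sa * zs
                fm_n = sa2 * e2im * fp + ca2 * fm + 1j * eim * sa * zs
                zs_n = -0.5j * eim * sa * fp + 0.5j * eip * sa * fm + ca * zs
                sig = np.abs(fp_n[0])
                if k_tr >= 2:
                    change = abs(sig - sig_prev)
                    # geometric extrapolation of the remaining transient;
                    # require a run of consecutive passes so early
                    # oscillatory near-zero changes do not exit prematurely
                    passed = False
                    if change < change_prev:
                        denom = change_prev - change
                        if denom > 0.0:
                            remaining = change * change / denom
                        else:
                            remaining = 0.0
                        passed = remaining < tol * max(sig, 1e-30)
                    if passed:
                        streak += 1
                    else:
                        streak = 0
                    if streak >= 3 and k_tr >= 20:
                        sig_out[i] = sig
                        ach[i] = remaining / max(sig, 1e-30)
                        done = True
                        break
                    change_prev = change
                elif k_tr == 1:
                    change_prev = abs(sig - sig_prev)
                sig_prev = sig
                fp_n *= e2
                fm_n *= e2
                zs_n *= e1
                zs_n[0] += 1.0 - e1
                for k in range(K - 1, 0, -1):
                    fp[k] = fp_n[k - 1]
                for k in range(K - 1):
                    fm[k] = fm_n[k + 1]
                fm[K - 1] = 0.0
                fp[0] = np.conj(fm_n[1])
                zs = zs_n
            if not done:
                sig_out[i] = sig_prev
                conv[i] = False
                ach[i] = remaining / max(sig_prev, 1e-30)
        return sig_out, conv, ach

    def _epg_batch(fa_deg, t1, t2, tr, inc_deg, n_tr, n_states, tol):
        sig, conv, ach = _epg_batch_kernel(
            np.ascontiguousarray(fa_deg, float), np.ascontiguousarray(t1, float),
            np.ascontiguousarray(t2, float), float(tr), float(inc_deg),
            int(n_tr), int(n_states), float(tol))
        return sig, bool(conv.all()), float(ach.max())

except Exception:  # pragma: no cover - numba absent
    def _epg_batch(fa_deg, t1, t2, tr, inc_deg, n_tr, n_states, tol):
        return _epg_batch_numpy(fa_deg, t1, t2, tr, inc_deg, n_tr, n_states, tol)


def epg_spoiled_signal_batch(fa_deg, t1, t2=30.0, tr=4.1,
                             rf_phase_increment=50.0, n_tr=4000,
                             n_states=None, steady_tol=1e-6):
    """Steady-state RF+gradient-spoiled SPGR signal magnitude per case.

    ``fa_deg`` and ``t1`` are broadcast 1-D arrays; ``t2`` may be scalar.
    The recursion stops when the geometrically extrapolated remaining
    transient falls below ``steady_tol`` of the signal (small flips approach
    steady state slowly, so a raw TR-to-TR change criterion underestimates
    the residual transient); otherwise it runs ``n_tr`` TRs and warns.
    Transverse configuration orders are truncated at ``n_states`` (default
    150, where the per-TR T2 decay makes higher orders negligible at liver
    T2/TR; tolerance documented in the methods note).
    """
    fa = np.atleast_1d(np.asarray(fa_deg, float))
    t1a = np.broadcast_to(np.asarray(t1, float), fa.shape).astype(float)
    t2a = np.broadcast_to(np.asarray(t2, float), fa.shape).astype(float)
    if n_states is None:
        n_states = min(int(n_tr), 150)
    sig, conv, ach = _epg_batch(fa, t1a, t2a, tr, rf_phase_increment,
                                n_tr, n_states, steady_tol)
    if not conv:
        warnings.warn(f"EPG signal not steady after {n_tr} TRs; estimated "
                      f"remaining relative transient {ach:.2e}",
                      RuntimeWarning, stacklevel=2)
    return sig


def epg_spoiled_signal(t1, t2, fa, tr, rf_phase_increment=50.0, n_tr=4000,
                       n_states=None, steady_tol=1e-6):
    """Scalar steady-state RF-spoiled SPGR signal (unit m0)."""
    return float(epg_spoiled_signal_batch(
        np.array([fa]), np.array([t1]), t2, tr, rf_phase_increment,
        n_tr, n_states, steady_tol)[0])


@dataclass
class SpoilingCorrection:
    """Tabulated EPG/Ernst signal ratio over (flip angle, T1).

    Queries outside the grid clamp to the edge with a logged warning.
    """

    fa_grid: np.ndarray
    t1_grid: np.ndarray
    table: np.ndarray
    t2: float
    acq: SPGRAcquisition

    def __post_init__(self):
        self._interp = RegularGridInterpolator(
            (self.fa_grid, self.t1_grid), self.table, method="linear",
            bounds_error=False, fill_value=None)

    def __call__(self, fa_deg, t1):
        fa = np.asarray(fa_deg, float)
        t1 = np.asarray(t1, float)
        out_of_range = (np.any(fa < self.fa_grid[0]) or np.any(fa > self.fa_grid[-1])
                        or np.any(t1 < self.t1_grid[0]) or np.any(t1 > self.t1_grid[-1]))
        if out_of_range:
            logger.warning("spoiling correction queried outside its grid; clamped")
        fa = np.clip(fa, self.fa_grid[0], self.fa_grid[-1])
        t1 = np.clip(t1, self.t1_grid[0], self.t1_grid[-1])
        pts = np.stack([fa, t1], axis=-1)
        out = self._interp(pts)
        return float(out) if out.ndim == 0 else out


def spoiling_correction(fa_grid=None, t1_grid=None, t2: float = 30.0,
                        acq: SPGRAcquisition = SPGRAcquisition(),
                        n_tr: int = 8000) -> SpoilingCorrection:
    """Tabulate the incomplete-spoiling correction epg/ideal over (fa, t1).

    Default grids cover the whole fit domain: B1+-scaled flips 0.1..40 deg
    (step 0.25 above 0.25 deg) and T1 geometrically spaced over the fit
    bounds 10..5000 ms; off-grid bilinear interpolation error is below 0.1%
    versus direct EPG (tested).
    """
    if fa_grid is None:
        fa_grid = np.concatenate([[0.1], np.arange(0.25, 40.0 + 1e-9, 0.25)])
    if t1_grid is None:
        t1_grid = np.geomspace(10.0, 5000.0, 80)
    fa_grid = np.asarray(fa_grid, float)
    t1_grid = np.asarray(t1_grid, float)
    if np.any(np.diff(fa_grid) <= 0) or np.any(np.diff(t1_grid) <= 0):
        raise ValueError("grids must be strictly increasing")
    ff, tt = np.meshgrid(fa_grid, t1_grid, indexing="ij")
    epg = epg_spoiled_signal_batch(ff.ravel(), tt.ravel(), t2, acq.tr,
                                   acq.rf_phase_increment, n_tr)
    ideal = spgr_ideal_signal(tt.ravel(), 1.0, ff.ravel(), acq.tr)
    table = (epg / ideal).reshape(ff.shape)
    return SpoilingCorrection(fa_grid, t1_grid, table, t2, acq)


_TABLE_CACHE: dict = {}


def default_spoiling_correction(acq: SPGRAcquisition,
                                t2: float = 30.0) -> SpoilingCorrection:
    """Memoized default spoiling-correction table for an acquisition."""
    key = (acq, float(t2))
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = spoiling_correction(t2=t2, acq=acq)
    return _TABLE_CACHE[key]
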