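"""Variable-flip-angle SPGR T1 mapping with B1+ and incomplete-spoiling
correction.

Per voxel the true flip angles are the nominal SPGR flips scaled by the
(interpolated) B1+ factor.  The fitted model is the Ernst steady state
multiplied by the tabulated EPG incomplete-spoiling correction; M0 enters
linearly and is profiled out, leaving a bounded 1-D NLLS in T1 initialized
from the linearized two-point DESPOT1 solution.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import minimize_scalar

from .epg import SPGRAcquisition, SpoilingCorrection, spgr_ideal_signal

logger = logging.getLogger(__name__)

__all__ = ["despot1_init", "fit_t1_voxels", "t1_slice_trend"]

T1_BOUNDS = (10.0, 5000.0)


def despot1_init(signals: np.ndarray, fas_deg: np.ndarray, tr: float) -> np.ndarray:
    """Linearized DESPOT1 T1 estimate per voxel.

    Regresses y = S/sin(a) on x = S/tan(a); the slope estimates E1 and
    T1 = -TR/ln(E1).  ``signals`` is (n_vox, n_fa).  Degenerate slopes fall
    back to 900 ms.
    """
    a = np.radians(np.asarray(fas_deg, float))
    y = signals / np.sin(a)
    x = signals / np.tan(a)
    xm = x.mean(axis=-1, keepdims=True)
    ym = y.mean(axis=-1, keepdims=True)
    denom = np.sum((x - xm) ** 2, axis=-1)
    num = np.sum((x - xm) * (y - ym), axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        e1 = np.where(denom > 0, num / np.maximum(denom, 1e-300), np.nan)
        t1 = np.where((e1 > 0) & (e1 < 1), -tr / np.log(e1), np.nan)
    t1 = np.where(np.isfinite(t1), t1, 900.0)
    return np.clip(t1, *T1_BOUNDS)


def _model_basis(t1: float, fas_deg: np.ndarray, acq: SPGRAcquisition,
                 corr: SpoilingCorrection | None) -> np.ndarray:
    """Signal per unit M0 at each flip angle for the given T1."""
    s = spgr_ideal_signal(t1, 1.0, fas_deg, acq.tr)
    if corr is not None:
        s = s * corr(fas_deg, np.full_like(fas_deg, t1))
    return s


def fit_t1_voxels(signals: np.ndarray, fas_deg: np.ndarray,
                  acq: SPGRAcquisition,
                  corr: SpoilingCorrection | None = None,
                  t1_bounds=T1_BOUNDS):
    """Voxelwise (T1, M0) fit of multi-flip-angle SPGR magnitudes.

    Parameters
    ----------
    signals : (n_vox, n_fa) magnitudes.
    fas_deg : (n_vox, n_fa) true flip angles per voxel (B1+-scaled).
    corr : optional incomplete-spoiling correction table.

    Returns dict with t1, m0, residual_norm, converged arrays (n_vox,).
    Voxels with any non-positive signal are excluded (NaN outputs, counted).
    """
    signals = np.asarray(signals, float)
    fas_deg = np.asarray(fas_deg, float)
    n_vox = signals.shape[0]
    t1_out = np.full(n_vox, np.nan)
    m0_out = np.full(n_vox, np.nan)
    res_out = np.full(n_vox, np.nan)
    conv = np.zeros(n_vox, bool)
    ok = np.all(signals > 0, axis=1) & np.all(np.isfinite(signals), axis=1)
    n_bad = int(np.sum(~ok))
    if n_bad:
        logger.warning("fit_t1_voxels: %d voxel(s) excluded (non-positive signal)", n_bad)
    t1_init = despot1_init(signals, fas_deg, acq.tr)

    lo, hi = t1_bounds
    for i in np.nonzero(ok)[0]:
        s = signals[i]
        fa = fas_deg[i]

        def cost(t1):
            b = _model_basis(t1, fa, acq, corr)
            bb = float(b @ b)
            if bb <= 0:
                return float(s @ s)
            m0 = max(float(s @ b) / bb, 0.0)   # m0 profiled out, kept positive
            r = s - m0 * b
            return float(r @ r)

        x0 = float(np.clip(t1_init[i], lo + 1, hi - 1))
        # bounded scalar minimization bracketed around the DESPOT1 start
        br_lo = max(lo, x0 / 4)
        br_hi = min(hi, x0 * 4)
        sol = minimize_scalar(cost, bounds=(br_lo, br_hi), method="bounded",
                              options={"xatol": 1e-3})
        # widen once if the solution pinned to an interior bracket edge
        if (abs(sol.x - br_lo) < 1e-2 and br_lo > lo) or \
           (abs(sol.x - br_hi) < 1e-2 and br_hi < hi):
            sol = minimize_scalar(cost, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-3})
        t1_hat = float(sol.x)
        b = _model_basis(t1_hat, fa, acq, corr)
        m0_hat = max(float(s @ b) / float(b @ b), 0.0)
        t1_out[i] = t1_hat
        m0_out[i] = m0_hat
        res_out[i] = float(np.linalg.norm(s - m0_hat * b))
        conv[i] = bool(sol.success)
    n_nc = int(np.sum(ok & ~conv))
    if n_nc:
        logger.warning("fit_t1_voxels: %d voxel(s) flagged non-converged", n_nc)
    return {"t1": t1_out, "m0": m0_out, "residual_norm": res_out,
            "converged": conv, "n_excluded": n_bad}


def t1_slice_trend(t1_map: np.ndarray, rois, n_slices: int | None = None):
    """Linear trend of ROI-mean T1 versus slice index.

    Parameters
    ----------
    t1_map : (nx, ny, n_slices) fitted T1 volume (NaN outside the fit).
    rois : sequence of (slice_index, center_x, center_y, diameter_px)
        circular regions; several ROIs per slice are averaged into one
        slice-mean observation each.
    n_slices : number of slices spanned by the map (default: map shape).

    Returns dict with slope (ms/slice), delta_t1 (= slope * n_slices),
     95% CI for delta_t1, and the per-slice mean table.
    """
    import statsmodels.api as sm

    t1_map = np.asarray(t1_map, float)
    if n_slices is None:
        n_slices = t1_map.shape[2]
    nx, ny = t1_map.shape[:2]
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    per_roi = {}
    for (s, cx, cy, diam) in rois:
        s = int(s)
        sel = (xx - cx) ** 2 + (yy - cy) ** 2 <= (diam / 2.0) ** 2
        vals = t1_map[sel, s]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            per_roi.setdefault(s, []).append(float(vals.mean()))
    slices = sorted(per_roi)
    dropped = sorted(set(int(r[0]) for r in rois) - set(slices))
    if dropped:
        logger.warning("t1_slice_trend: slice(s) %s dropped (all ROIs empty)", dropped)
    if len(slices) < 2:
        raise ValueError("need ROI data on at least 2 slices")
    x = np.array(slices, float)
    y = np.array([np.mean(per_roi[s]) for s in slices])
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    ci = fit.conf_int(alpha=0.05)
    return {
        "slope_ms_per_slice": slope,
        "slope_se": se,
        "delta_t1": slope * n_slices,
        "delta_t1_ci": (float(ci[1][0]) * n_slices, float(ci[1][1]) * n_slices),
        "n_slices": n_slices,
        "slice_means": dict(zip(slices, y.tolist())),
        "intercept": float(fit.params[0]),
    }
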