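"""Model/Results interface for B1+ mapping and VFA T1 mapping.

`DoubleAngleModel` wraps a DAM magnitude pair and fits a B1+ factor map by
one of three methods: the naive arccos inversion, the slice-profile LUT
inversion, or the full per-voxel NLLS including the through-slice B0
gradient.  `VFAT1Model` wraps multi-flip-angle SPGR volumes plus a fitted
B1+ map and fits voxelwise T1/M0.  Both return Results objects carrying the
maps, per-voxel diagnostics and a `summary()` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .b0model import ThroughSliceB0Model
from .b1fit import B1_BOUNDS, correct_b1_batch
from .bloch import SliceSelection, TissueParams
from .epg import SPGRAcquisition, SpoilingCorrection, spoiling_correction
from .lut import RatioLUT, dam_naive_fa, invert_lut
from .pulses import RFPulse
from .t1fit import T1_BOUNDS, fit_t1_voxels, t1_slice_trend

logger = logging.getLogger(__name__)

__all__ = ["DoubleAngleModel", "B1MapResult", "VFAT1Model", "T1MapResult"]


@dataclass
class B1MapResult:
    """Voxelwise B1+ factor map with mask, method tag and diagnostics."""

    b1_factor: np.ndarray        # NaN outside mask / excluded voxels
    mask: np.ndarray
    method: str                  # naive | slice_profile | slice_profile+b0grad
    diagnostics: dict = field(default_factory=dict)

    def error_vs(self, b1_true: np.ndarray) -> np.ndarray:
        """Percent B1+ factor error against a reference field (NaN-safe)."""
        return 100.0 * (self.b1_factor - b1_true) / b1_true

    def plot(self, slice_index: int = 7, ax=None, **imshow_kw):
        """QC image of the B1+ factor map for one slice."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.b1_factor[:, :, slice_index].T, origin="lower",
                       **{"cmap": "viridis", **imshow_kw})
        ax.set_title(f"B1+ factor ({self.method}), slice {slice_index}")
        plt.colorbar(im, ax=ax, label="B1+ factor")
        return ax

    def summary(self) -> pd.DataFrame:
        """Per-slice median and IQR of the fitted B1+ factor."""
        rows = []
        for s in range(self.b1_factor.shape[2]):
            vals = self.b1_factor[:, :, s]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append({"slice": s, "n_voxels": vals.size, "median_b1": med,
                         "iqr_low": q1, "iqr_high": q3})
        df = pd.DataFrame(rows)
        df.attrs["method"] = self.method
        return df


class DoubleAngleModel:
    """Double-angle B1+ mapping model over a DAM magnitude image pair.

    Parameters
    ----------
    img_alpha, img_2alpha : (nx, ny, n_slices) magnitude volumes at the
        nominal flip-angle pair (alpha, 2*alpha).
    nominal_alpha : nominal flip angle of the first image, degrees.
    mask : boolean volume restricting the fit.
    lut : slice-profile ratio LUT (required for the LUT and B0-corrected
        methods); its acquisition context supplies the Bloch geometry.
    pulse, slice_sel, te, tissue : Bloch context for the B0-corrected fit.
    """

    def __init__(self, img_alpha, img_2alpha, nominal_alpha: float = 65.0,
                 mask=None, lut: RatioLUT | None = None,
                 pulse: RFPulse | None = None,
                 slice_sel: SliceSelection | None = None,
                 te: float = 11.0, tissue: TissueParams = TissueParams()):
        self.img_alpha = np.asarray(img_alpha, float)
        self.img_2alpha = np.asarray(img_2alpha, float)
        if self.img_alpha.shape != self.img_2alpha.shape:
            raise ValueError("image shapes differ: "
                             f"{self.img_alpha.shape} vs {self.img_2alpha.shape}")
        self.nominal_alpha = float(nominal_alpha)
        self.mask = (np.ones(self.img_alpha.shape, bool) if mask is None
                     else np.asarray(mask, bool))
        if self.mask.shape != self.img_alpha.shape:
            raise ValueError("mask shape does not match images")
        self.lut = lut
        self.pulse = pulse
        self.slice_sel = slice_sel
        self.te = te
        self.tissue = tissue

    # ------------------------------------------------------------------
    def _masked_ratio(self):
        ii, jj, ss = np.nonzero(self.mask)
        s1 = self.img_alpha[ii, jj, ss]
        s2 = self.img_2alpha[ii, jj, ss]
        ok = s1 > 0
        n_zero = int(np.sum(~ok))
        if n_zero:
            logger.warning("%d masked voxel(s) with S1 <= 0 set missing", n_zero)
        ratio = np.full(s1.shape, np.nan)
        ratio[ok] = s2[ok] / s1[ok]
        return (ii, jj, ss), ratio, n_zero

    def _finalize(self, idx, b1_vals, method, diag):
        out = np.full(self.img_alpha.shape, np.nan)
        lo, hi = B1_BOUNDS
        clipped = np.clip(b1_vals, lo, hi)
        n_clip = int(np.nansum(np.abs(clipped - b1_vals) > 0))
        if n_clip:
            logger.warning("%d fitted B1+ value(s) clipped to bounds", n_clip)
        out[idx] = clipped
        diag = dict(diag, n_clipped=n_clip)
        return B1MapResult(out, self.mask.copy(), method, diag)

    # ------------------------------------------------------------------
    def fit(self, method: str = "slice_profile",
            b0_model: ThroughSliceB0Model | None = None,
            slice_centers=None) -> B1MapResult:
        """Fit the B1+ factor map.

        method : 'naive' (Eq. arccos inversion), 'slice_profile' (LUT), or
        'b0_corrected' (per-voxel NLLS with the through-slice B0 profile
        from ``b0_model``, initialized from the slice-profile fit).
        """
        if method == "naive":
            return self._fit_naive()
        if method == "slice_profile":
            return self._fit_slice_profile()
        if method == "b0_corrected":
            return self._fit_b0_corrected(b0_model, slice_centers)
        raise ValueError(f"unknown method {method!r}")

    def _fit_naive(self):
        idx, ratio, n_zero = self._masked_ratio()
        fa = np.full(ratio.shape, np.nan)
        good = np.isfinite(ratio)
        fa[good] = dam_naive_fa(1.0, ratio[good])
        return self._finalize(idx, fa / self.nominal_alpha, "naive",
                              {"n_missing": n_zero})

    def _fit_slice_profile(self):
        if self.lut is None:
            raise ValueError("slice_profile method requires a ratio LUT")
        idx, ratio, n_zero = self._masked_ratio()
        fa = invert_lut(self.lut, ratio)
        return self._finalize(idx, fa / self.nominal_alpha, "slice_profile",
                              {"n_missing": n_zero})

    def _fit_b0_corrected(self, b0_model, slice_centers):
        if b0_model is None:
            raise ValueError("b0_corrected method requires a ThroughSliceB0Model")
        if self.lut is None or self.pulse is None or self.slice_sel is None:
            raise ValueError("b0_corrected method requires lut, pulse and slice_sel")
        if slice_centers is None:
            slice_centers = b0_model.slice_centers
        slice_centers = np.asarray(slice_centers, float)
        if slice_centers.size != self.img_alpha.shape[2]:
            raise ValueError("slice_centers length must equal the number of slices")

        idx, ratio, n_zero = self._masked_ratio()
        ii, jj, ss = idx
        init_fa = invert_lut(self.lut, ratio)
        init_b1 = np.clip(init_fa / self.nominal_alpha, *B1_BOUNDS)

        z = self.slice_sel.z_grid
        fa_pair = (self.nominal_alpha, 2 * self.nominal_alpha)
        b1_out = np.full(ratio.shape, np.nan)
        res_out = np.full(ratio.shape, np.nan)
        conv_out = np.zeros(ratio.shape, bool)
        iters_out = np.zeros(ratio.shape, int)
        n_extrap = 0
        per_slice = []
        for s in np.unique(ss):
            sel = (ss == s) & np.isfinite(ratio) & (ratio > 0)
            if not np.any(sel):
                continue
            pix = np.column_stack([ii[sel], jj[sel]])
            have = np.array([b0_model.has_pixel(i, j) for i, j in pix])
            if not np.all(have):
                logger.warning("slice %d: %d voxel(s) without B0 model dropped",
                               s, int(np.sum(~have)))
            sel_idx = np.nonzero(sel)[0][have]
            if sel_idx.size == 0:
                continue
            z_eval = slice_centers[s] + z
            n_extrap += int(np.any(b0_model.is_extrapolated(z_eval))) * sel_idx.size
            profs = b0_model.evaluate_pixels(
                np.column_stack([ii[sel_idx], jj[sel_idx]]), z_eval)
            b1_s, res_s, it_s, cv_s = correct_b1_batch(
                ratio[sel_idx], profs, init_b1[sel_idx], self.pulse,
                self.slice_sel, self.te, self.tissue, fa_pair)
            b1_out[sel_idx] = b1_s
            res_out[sel_idx] = res_s
            conv_out[sel_idx] = cv_s
            iters_out[sel_idx] = it_s
            per_slice.append({"slice": int(s), "n_fit": int(sel_idx.size),
                              "n_converged": int(cv_s.sum()),
                              "mean_iterations": float(it_s.mean())})
        diag = {"n_missing": n_zero, "per_slice": per_slice,
                "n_extrapolated_support": n_extrap,
                "residual": self._scatter(idx, res_out),
                "converged": self._scatter(idx, conv_out.astype(float)),
                "init_b1": self._scatter(idx, init_b1)}
        return self._finalize(idx, b1_out, "slice_profile+b0grad", diag)

    def _scatter(self, idx, vals):
        vol = np.full(self.img_alpha.shape, np.nan)
        vol[idx] = vals
        return vol


@dataclass
class T1MapResult:
    """Voxelwise T1/M0 fit with diagnostics and slice-trend analysis."""

    t1: np.ndarray               # ms, NaN outside fit
    m0: np.ndarray
    residual_norm: np.ndarray
    converged: np.ndarray
    mask: np.ndarray
    b1_method: str = "unknown"
    n_excluded: int = 0

    def summary(self) -> pd.DataFrame:
        rows = []
        for s in range(self.t1.shape[2]):
            vals = self.t1[:, :, s]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append({"slice": s, "n_voxels": vals.size,
                         "median_t1_ms": med, "iqr_low": q1, "iqr_high": q3})
        df = pd.DataFrame(rows)
        df.attrs["b1_method"] = self.b1_method
        return df

    def slice_trend(self, rois, n_slices: int | None = None) -> dict:
        """Linear fit of ROI-mean T1 versus slice; delta T1 = slope x slices."""
        return t1_slice_trend(self.t1, rois, n_slices)

    def plot(self, slice_index: int = 7, ax=None, **imshow_kw):
        """QC image of the fitted T1 map for one slice (ms)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.t1[:, :, slice_index].T, origin="lower",
                       **{"cmap": "magma", **imshow_kw})
        ax.set_title(f"T1 (B1+ {self.b1_method}), slice {slice_index}")
        plt.colorbar(im, ax=ax, label="T1 (ms)")
        return ax


class VFAT1Model:
    """Variable-flip-angle SPGR T1 mapping model.

    Parameters
    ----------
    volumes : (nx, ny, n_slices, n_fa) SPGR magnitudes (or list of 3-D
        volumes) matching ``acq.nominal_fas``.
    acq : SPGR acquisition parameters.
    b1map : B1MapResult or B1+ factor array; trilinearly resampled to the
        SPGR grid when shapes differ.
    mask : boolean volume restricting the fit.
    spoiling : SpoilingCorrection table, True to build the default one,
        or None/False for the ideal Ernst model.
    """

    def __init__(self, volumes, acq: SPGRAcquisition, b1map, mask=None,
                 spoiling: SpoilingCorrection | bool | None = True):
        if isinstance(volumes, (list, tuple)):
            volumes = np.stack(volumes, axis=-1)
        self.volumes = np.asarray(volumes, float)
        if self.volumes.ndim != 4 or self.volumes.shape[3] != len(acq.nominal_fas):
            raise ValueError("volumes must be (nx, ny, n_slices, n_fa) matching acq")
        self.acq = acq
        b1 = b1map.b1_factor if isinstance(b1map, B1MapResult) else np.asarray(b1map, float)
        self.b1_method = b1map.method if isinstance(b1map, B1MapResult) else "external"
        self.b1 = self._resample_to_grid(b1, self.volumes.shape[:3])
        self.mask = (np.isfinite(self.b1) if mask is None
                     else np.asarray(mask, bool) & np.isfinite(self.b1))
        if spoiling is True:
            from .epg import default_spoiling_correction
            spoiling = default_spoiling_correction(acq)
        self.spoiling = spoiling or None

    @staticmethod
    def _resample_to_grid(arr, shape):
        if arr.shape == tuple(shape):
            return arr
        from scipy.ndimage import zoom
        filled = np.nan_to_num(arr, nan=1.0)
        factors = [t / s for t, s in zip(shape, arr.shape)]
        out = zoom(filled, factors, order=1)
        # re-impose missingness from the nearest-neighbour resampled mask
        missing = zoom((~np.isfinite(arr)).astype(float), factors, order=0) > 0.5
        out[missing] = np.nan
        return out

    def fit(self) -> T1MapResult:
        ii, jj, ss = np.nonzero(self.mask)
        sig = self.volumes[ii, jj, ss, :]
        fas = self.b1[ii, jj, ss, None] * np.asarray(self.acq.nominal_fas, float)
        res = fit_t1_voxels(sig, fas, self.acq, self.spoiling, T1_BOUNDS)
        shape = self.volumes.shape[:3]

        def scatter(v, fill=np.nan, dtype=float):
            out = np.full(shape, fill, dtype=dtype)
            out[ii, jj, ss] = v
            return out

        return T1MapResult(
            t1=scatter(res["t1"]), m0=scatter(res["m0"]),
            residual_norm=scatter(res["residual_norm"]),
            converged=scatter(res["converged"], fill=False, dtype=bool),
            mask=self.mask.copy(), b1_method=self.b1_method,
            n_excluded=res["n_excluded"])
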