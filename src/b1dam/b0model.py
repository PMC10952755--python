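"""Per-pixel cubic-spline model of B0 along the slice direction.

A multi-slice field map samples B0 (Hz) at the slice-center positions.  For
every in-plane pixel the samples are interpolated with a cubic spline
(not-a-knot end conditions, so polynomial fields up to cubic are reproduced
exactly) so that the field can be evaluated continuously over the +/-1 cm
neighborhood of any slice center.  Beyond the sampled slice range the
spline's end cubic is continued (the edge slices need the field half a
slice past the last center, where a constant clamp would zero the local
gradient and bias the correction exactly where it matters most); such
evaluations are flagged via :meth:`ThroughSliceB0Model.is_extrapolated`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

__all__ = ["ThroughSliceB0Model", "fit_b0_spline"]


@dataclass
class ThroughSliceB0Model:
    """Cubic-spline B0(z) model for each masked in-plane pixel.

    Attributes
    ----------
    shape : (nx, ny) in-plane grid shape.
    slice_centers : (n_slices,) through-slice positions, cm.
    pixel_index : (n_pixels, 2) integer in-plane coordinates with a model.
    fallback_flags : (n_pixels,) True where fewer than 4 valid slices forced
        a lower-order polynomial fit instead of a cubic spline.
    """

    shape: tuple
    slice_centers: np.ndarray
    pixel_index: np.ndarray
    fallback_flags: np.ndarray
    n_excluded: int
    _evaluators: list = field(repr=False, default_factory=list)
    _pix_lookup: dict = field(repr=False, default_factory=dict)

    def has_pixel(self, i: int, j: int) -> bool:
        return (i, j) in self._pix_lookup

    def evaluate(self, i: int, j: int, z: np.ndarray) -> np.ndarray:
        """B0 (Hz) at through-slice positions ``z`` (cm) for pixel (i, j);
        outside the sampled slice-center range the end cubic is continued."""
        k = self._pix_lookup.get((i, j))
        if k is None:
            raise KeyError(f"no B0 model at pixel ({i}, {j})")
        return self._evaluators[k](np.asarray(z, float))

    def evaluate_pixels(self, pixels: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Evaluate many pixels on a shared z grid -> (n_pixels, n_z)."""
        out = np.empty((len(pixels), np.asarray(z).size))
        for r, (i, j) in enumerate(pixels):
            out[r] = self.evaluate(int(i), int(j), z)
        return out

    def is_extrapolated(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, float)
        return (z < self.slice_centers[0]) | (z > self.slice_centers[-1])


def fit_b0_spline(b0_stack: np.ndarray, slice_centers: np.ndarray,
                  mask: np.ndarray | None = None) -> ThroughSliceB0Model:
    """Fit per-pixel cubic splines through (slice_center, B0) samples.

    Parameters
    ----------
    b0_stack : (nx, ny, n_slices) field map in Hz; NaN marks invalid samples.
    slice_centers : (n_slices,) strictly increasing positions in cm.
    mask : optional (nx, ny, n_slices) boolean; a pixel's valid slices are
        those masked-in with finite B0.  Pixels with >= 4 valid slices get a
        cubic spline; 2-3 valid slices fall back to the highest feasible
        polynomial order (flagged); < 2 are excluded (counted).
    """
    b0_stack = np.asarray(b0_stack, float)
    slice_centers = np.asarray(slice_centers, float)
    if b0_stack.ndim != 3 or b0_stack.shape[2] != slice_centers.size:
        raise ValueError("b0_stack must be (nx, ny, n_slices) matching slice_centers")
    if slice_centers.size < 4:
        raise ValueError("need >= 4 slices for cubic through-slice interpolation")
    if np.any(np.diff(slice_centers) <= 0):
        raise ValueError("slice_centers must be strictly increasing")
    nx, ny, ns = b0_stack.shape
    valid = np.isfinite(b0_stack)
    if mask is not None:
        valid &= np.asarray(mask, bool)

    counts = valid.sum(axis=2)
    candidate = np.argwhere(counts >= 2)
    evaluators: list = []
    pix_lookup: dict = {}
    pixel_index = []
    fallback_flags = []
    n_excluded = int(np.sum((counts > 0) & (counts < 2)))

    # group pixels by validity pattern so one vector spline serves each group
    patterns: dict = {}
    for i, j in candidate:
        patterns.setdefault(valid[i, j].tobytes(), []).append((i, j))

    for pat, pixels in patterns.items():
        vmask = np.frombuffer(pat, dtype=bool)
        x = slice_centers[vmask]
        ij = np.array(pixels)
        y = b0_stack[ij[:, 0], ij[:, 1]][:, vmask].T  # (n_valid, n_pix)
        if x.size >= 4:
            cs = CubicSpline(x, y, axis=0, bc_type="not-a-knot")
            fb = False
            def make_eval(cs=cs, col=None):
                return lambda z: cs(z)[..., col]
            for col, (i, j) in enumerate(pixels):
                pix_lookup[(int(i), int(j))] = len(evaluators)
                evaluators.append(make_eval(col=col))
                pixel_index.append((i, j))
                fallback_flags.append(fb)
        else:
            deg = x.size - 1
            coef = np.polyfit(x, y, deg)
            for col, (i, j) in enumerate(pixels):
                c = coef[:, col]
                pix_lookup[(int(i), int(j))] = len(evaluators)
                evaluators.append(lambda z, c=c: np.polyval(c, z))
                pixel_index.append((i, j))
                fallback_flags.append(True)
    n_fb = int(np.sum(fallback_flags))
    if n_fb:
        logger.warning("fit_b0_spline: %d pixel(s) used a low-order fallback fit", n_fb)
    if n_excluded:
        logger.warning("fit_b0_spline: %d pixel(s) excluded (<2 valid slices)", n_excluded)
    return ThroughSliceB0Model(
        shape=(nx, ny), slice_centers=slice_centers,
        pixel_index=np.array(pixel_index, int).reshape(-1, 2),
        fallback_flags=np.array(fallback_flags, bool),
        n_excluded=n_excluded,
        _evaluators=evaluators, _pix_lookup=pix_lookup)
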