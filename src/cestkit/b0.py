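"""WASSR-based B0 estimation and Z-spectrum re-referencing.

The water saturation shift referencing (WASSR) scan is a low-power,
water-only Z-spectrum: its minimum sits at the local water resonance, so
the frequency of the interpolated minimum is the per-voxel B0 offset.
Each CEST spectrum is then resampled at ``axis + b0`` and reported on the
nominal axis, putting its water line back at 0 ppm.  Points that would
require extrapolation beyond the measured range are marked missing, never
extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .axis import validate_axis
from .lorentzfit import ZSpectrum

__all__ = ["B0Error", "B0Map", "estimate_b0", "correct_zspectrum",
           "estimate_b0_map", "correct_stack"]


class B0Error(ValueError):
    """Raised when a voxel's B0 cannot be estimated or applied."""


@dataclass
class B0Map:
    """Per-voxel B0 offset (ppm) with a validity mask."""

    offset: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.offset = np.asarray(self.offset, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.offset.shape != self.valid.shape:
            raise ValueError("offset and valid shapes differ")


def _interpolator(axis: np.ndarray, values: np.ndarray):
    # cubic spline on >=5 points, linear fallback below (spline needs 4;
    # keep one in hand for stability)
    if axis.size >= 5:
        return CubicSpline(axis, values)
    return lambda x: np.interp(x, axis, values)


def estimate_b0(wassr: ZSpectrum | np.ndarray, axis: np.ndarray,
                upsample: int = 100, bound: float = 1.0) -> float:
    """Locate the water minimum of a WASSR spectrum at sub-step resolution.

    The spectrum is upsampled ``upsample``-fold with a smooth interpolant
    and the argmin taken.  A minimum on the axis boundary (water line out
    of the sampled window), a flat spectrum, or ``|b0| > bound`` raises
    :class:`B0Error` — such voxels are invalid, never silently zeroed.
    """
    if not isinstance(wassr, ZSpectrum):
        wassr = ZSpectrum(np.asarray(wassr))
    axis = validate_axis(axis, min_points=7)
    if wassr.values.shape != axis.shape:
        raise B0Error("WASSR spectrum and axis lengths differ")
    if wassr.n_valid < 7:
        raise B0Error(f"need >= 7 valid points, got {wassr.n_valid}")
    ax = axis[wassr.mask]
    vals = wassr.values[wassr.mask]
    if np.ptp(vals) < 1e-9:
        raise B0Error("flat spectrum: no water minimum")
    fine = np.linspace(ax[0], ax[-1], (ax.size - 1) * upsample + 1)
    interp = _interpolator(ax, vals)
    k = int(np.argmin(interp(fine)))
    if k == 0 or k == fine.size - 1:
        raise B0Error("spectral minimum on axis boundary: water line out of window")
    b0 = float(fine[k])
    if abs(b0) > bound:
        raise B0Error(f"|b0| = {abs(b0):.3f} ppm exceeds bound {bound} ppm")
    return b0


def correct_zspectrum(z: ZSpectrum | np.ndarray, axis: np.ndarray, b0: float,
                      bound: float = 1.0, max_missing_frac: float = 0.2) -> ZSpectrum:
    """Re-reference one Z-spectrum onto the nominal axis.

    The measured spectrum (whose water line sits at ``b0``) is interpolated
    at ``axis + b0``; the result, reported on the nominal axis, has its
    water minimum at 0 ppm.  Offsets falling outside the measured range
    become NaN with a False mask.  If the shift would invalidate more than
    ``max_missing_frac`` of the previously valid points the voxel is
    rejected with :class:`B0Error`.
    """
    if not isinstance(z, ZSpectrum):
        z = ZSpectrum(np.asarray(z))
    axis = validate_axis(axis)
    if z.values.shape != axis.shape:
        raise B0Error("spectrum and axis lengths differ")
    if abs(b0) > bound:
        raise B0Error(f"|b0| = {abs(b0):.3f} ppm exceeds bound {bound} ppm")
    if b0 == 0.0:
        return ZSpectrum(z.values.copy(), z.mask.copy())
    ax = axis[z.mask]
    vals = z.values[z.mask]
    if ax.size < 2:
        raise B0Error("too few valid points to interpolate")
    target = axis + b0
    inside = (target >= ax[0]) & (target <= ax[-1])
    out_vals = np.full(axis.shape, np.nan)
    interp = _interpolator(ax, vals)
    out_vals[inside] = interp(target[inside])
    out_mask = z.mask & inside
    n_before = z.n_valid
    n_lost = n_before - int(out_mask.sum())
    if n_lost > max_missing_frac * n_before:
        raise B0Error(
            f"correction by {b0:+.3f} ppm would drop {n_lost}/{n_before} points "
            f"(> {max_missing_frac:.0%})"
        )
    return ZSpectrum(out_vals, out_mask)


def estimate_b0_map(wassr_stack: np.ndarray, axis: np.ndarray,
                    mask: np.ndarray | None = None, upsample: int = 100,
                    bound: float = 1.0) -> B0Map:
    """Voxelwise :func:`estimate_b0`; failures become invalid-mask entries."""
    wassr_stack = np.asarray(wassr_stack, dtype=float)
    axis = validate_axis(axis, min_points=7)
    if wassr_stack.shape[-1] != axis.size:
        raise B0Error(
            f"stack last dimension {wassr_stack.shape[-1]} != axis length {axis.size}"
        )
    spatial = wassr_stack.shape[:-1]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    if mask.shape != spatial:
        raise B0Error(f"mask shape {mask.shape} != stack spatial shape {spatial}")
    offset = np.full(spatial, np.nan)
    valid = np.zeros(spatial, dtype=bool)
    for idx in map(tuple, np.argwhere(mask)):
        try:
            offset[idx] = estimate_b0(wassr_stack[idx], axis, upsample, bound)
            valid[idx] = True
        except B0Error:
            pass
    return B0Map(offset=offset, valid=valid)


def correct_stack(z_stack: np.ndarray, axis: np.ndarray, b0_map: B0Map,
                  bound: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise re-referencing of a Z-spectrum stack.

    Returns ``(corrected, mask)`` where ``corrected`` has NaN at missing
    points and ``mask`` is the per-voxel, per-offset validity.  Voxels
    invalid in the B0 map, or rejected during correction, come back fully
    masked.
    """
    z_stack = np.asarray(z_stack, dtype=float)
    axis = validate_axis(axis)
    spatial = z_stack.shape[:-1]
    if z_stack.shape[-1] != axis.size:
        raise B0Error(
            f"stack last dimension {z_stack.shape[-1]} != axis length {axis.size}"
        )
    if b0_map.offset.shape != spatial:
        raise B0Error(
            f"B0 map shape {b0_map.offset.shape} != stack spatial shape {spatial}"
        )
    out = np.full_like(z_stack, np.nan)
    out_mask = np.zeros(z_stack.shape, dtype=bool)
    for idx in map(tuple, np.argwhere(b0_map.valid)):
        try:
            zc = correct_zspectrum(z_stack[idx], axis, float(b0_map.offset[idx]), bound)
        except B0Error:
            continue
        out[idx] = zc.values
        out_mask[idx] = zc.mask
    return out, out_mask
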