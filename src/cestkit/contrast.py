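"""CEST contrast: area under each fitted Lorentzian, per voxel.

The per-metabolite contrast is the area under the pool's fitted
Lorentzian.  Two modes: ``analytic`` — the full-line integral
``A * pi * Gamma / 2``, scale-consistent across pools of different
linewidth; ``numeric`` — the trapezoidal integral of the fitted curve over
a finite window (default the ±5 ppm acquisition window).  The closed-form
fraction of a Lorentzian's mass inside a window links the two:

    frac = (arctan(2(b - d)/G) - arctan(2(a - d)/G)) / pi
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lorentzfit import FitResult, FitResultStack, lorentzian

__all__ = ["ContrastMap", "ContrastError", "pool_auc", "lorentzian_window_fraction",
           "contrast_map", "render_heatmap"]

DEFAULT_WINDOW = (-5.0, 5.0)


class ContrastError(ValueError):
    """Raised for contrast-map structural problems."""


@dataclass
class ContrastMap:
    """Per-voxel AUC for one pool (units: ppm x normalized signal)."""

    values: np.ndarray
    mask: np.ndarray
    pool: str
    mode: str
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ContrastError("values and mask shapes differ")


def _analytic_auc(amplitude: float, fwhm: float) -> float:
    return amplitude * np.pi * fwhm / 2.0


def lorentzian_window_fraction(center: float, fwhm: float,
                               window: tuple[float, float]) -> float:
    """Closed-form fraction of a Lorentzian's total area inside ``window``."""
    a, b = window
    if b <= a:
        raise ContrastError(f"window min must be < max, got {window}")
    return float((np.arctan(2.0 * (b - center) / fwhm)
                  - np.arctan(2.0 * (a - center) / fwhm)) / np.pi)


def pool_auc(fit: FitResult, pool: str, mode: str = "analytic",
             window: tuple[float, float] = DEFAULT_WINDOW,
             numeric_step: float = 0.001) -> float:
    """Area under one fitted pool's Lorentzian.

    ``analytic`` integrates over the whole line; ``numeric`` trapezoids the
    fitted curve over ``window``.
    """
    p = fit.pool(pool)  # KeyError for unknown pool names
    if mode == "analytic":
        return _analytic_auc(p.amplitude, p.fwhm)
    if mode == "numeric":
        a, b = window
        if b <= a:
            raise ContrastError(f"window min must be < max, got {window}")
        step = min(numeric_step, p.fwhm / 50.0)
        x = np.linspace(a, b, int(np.ceil((b - a) / step)) + 1)
        return float(np.trapezoid(lorentzian(x, p.amplitude, p.center, p.fwhm), x))
    raise ContrastError(f"unknown AUC mode {mode!r} (use 'analytic' or 'numeric')")


def contrast_map(fits: FitResultStack, pool: str, mode: str = "analytic",
                 window: tuple[float, float] = DEFAULT_WINDOW) -> ContrastMap:
    """AUC applied per voxel; non-converged or unfitted voxels stay masked."""
    if pool not in fits.amplitude:
        raise KeyError(f"no pool named {pool!r}; have {fits.pool_names()}")
    ok = fits.fitted & fits.converged
    if not ok.any():
        raise ContrastError("no valid voxels: all masked or non-converged")
    amp = fits.amplitude[pool]
    fwhm = fits.fwhm[pool]
    cen = fits.center[pool]
    values = np.full(ok.shape, np.nan)
    if mode == "analytic":
        values[ok] = amp[ok] * np.pi * fwhm[ok] / 2.0
    elif mode == "numeric":
        a, b = window
        if b <= a:
            raise ContrastError(f"window min must be < max, got {window}")
        # closed-form window fraction x analytic area == trapezoid limit
        frac = (np.arctan(2.0 * (b - cen[ok]) / fwhm[ok])
                - np.arctan(2.0 * (a - cen[ok]) / fwhm[ok])) / np.pi
        values[ok] = amp[ok] * np.pi * fwhm[ok] / 2.0 * frac
    else:
        raise ContrastError(f"unknown AUC mode {mode!r}")
    return ContrastMap(values=values, mask=ok, pool=pool, mode=mode,
                       window=window if mode == "numeric" else None)


def render_heatmap(cmap: ContrastMap, out_path, underlay: np.ndarray | None = None,
                   window: tuple[float, float] | None = None,
                   colormap: str = "inferno", dpi: int = 120) -> None:
    """Write a color-mapped contrast overlay as PNG.

    ``window`` fixes the color limits so maps from different arms are
    directly comparable; limits and colormap are printed in the figure
    margin.  Rendering is deterministic: the same map and window produce a
    byte-identical file.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if underlay is not None:
        underlay = np.asarray(underlay, dtype=float)
        if underlay.shape != cmap.values.shape:
            raise ContrastError(
                f"underlay shape {underlay.shape} != map shape {cmap.values.shape}"
            )
    if window is None:
        finite = cmap.values[cmap.mask]
        window = (float(np.nanmin(finite)), float(np.nanmax(finite)))
    vmin, vmax = window
    if vmin >= vmax:
        raise ContrastError(f"window min must be < max, got {window}")

    fig, ax = plt.subplots(figsize=(4, 4))
    if underlay is not None:
        ax.imshow(underlay.T, cmap="gray", origin="lower", interpolation="nearest")
    shown = np.ma.masked_where(~cmap.mask, cmap.values)
    im = ax.imshow(shown.T, cmap=colormap, origin="lower", vmin=vmin, vmax=vmax,
                   interpolation="nearest")
    ax.set_axis_off()
    fig.colorbar(im, ax=ax, fraction=0.046, pad=0.04)
    fig.text(0.01, 0.01,
             f"{cmap.pool} AUC [{cmap.mode}] window=[{vmin:.4g}, {vmax:.4g}] "
             f"cmap={colormap}", fontsize=6)
    fig.savefig(out_path, dpi=dpi, metadata={"Software": "cestkit"})
    plt.close(fig)
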