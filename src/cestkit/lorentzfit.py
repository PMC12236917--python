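"""Multi-pool Lorentzian decomposition of Z-spectra.

The model is the standard sum-of-Lorentzians for a normalized Z-spectrum:

    Z(dw) = 1 - sum_i L_i(dw),
    L_i(dw) = A_i * (G_i/2)^2 / ((G_i/2)^2 + (dw - d_i)^2)

with amplitude A_i, center d_i (ppm) and full width at half maximum G_i
(ppm).  Fitting is bounded nonlinear least squares (trust-region reflective)
with an analytic Jacobian; solute/MT/NOE centers are fixed by default and
the water center floats within a small window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .axis import validate_axis
from .pools import PoolSpec, default_pools

__all__ = [
    "lorentzian",
    "model_pools",
    "model_5pool",
    "ZSpectrum",
    "FitConfig",
    "FitResult",
    "FitResultStack",
    "FitError",
    "fit_zspectrum",
    "fit_stack",
]

log = logging.getLogger(__name__)


class FitError(RuntimeError):
    """Raised when a spectrum cannot be fitted at all (bad inputs)."""


def lorentzian(delta_omega, amplitude: float, center: float, fwhm: float):
    """Amplitude-normalized Lorentzian: ``A`` at its center, ``A/2`` at ±FWHM/2.

    Parameters are amplitude ``A`` (dimensionless), center (ppm) and FWHM
    (ppm, must be positive).  Vectorized over ``delta_omega``.
    """
    if fwhm <= 0:
        raise ValueError(f"fwhm must be > 0, got {fwhm}")
    hw2 = (0.5 * fwhm) ** 2
    d = np.asarray(delta_omega, dtype=float) - center
    return amplitude * hw2 / (hw2 + d * d)


def model_pools(pools: list[PoolSpec], axis: np.ndarray) -> np.ndarray:
    """Evaluate ``Z = 1 - sum of pool Lorentzians`` on ``axis``."""
    axis = np.asarray(axis, dtype=float)
    z = np.ones_like(axis)
    for p in pools:
        z -= lorentzian(axis, p.amplitude, p.center, p.fwhm)
    return z


#: alias emphasising the five-pool configuration used throughout
model_5pool = model_pools


@dataclass
class ZSpectrum:
    """Normalized saturated signal S/S0 per offset, with a validity mask."""

    values: np.ndarray
    mask: np.ndarray | None = None  # True = usable point

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool) & np.isfinite(self.values)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask and values shapes differ")

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())


@dataclass
class FitConfig:
    """Fit configuration: pool table plus solver controls.

    ``tol`` is applied as ftol/xtol/gtol of the least-squares solver;
    ``multi_start`` > 0 adds that many seeded jittered restarts (off by
    default — the deterministic single start passes the exact-recovery
    oracle and keeps voxelwise fitting cheap).
    """

    pools: list[PoolSpec] = field(default_factory=default_pools)
    tol: float = 1e-10
    max_nfev: int = 500
    multi_start: int = 0
    multi_start_seed: int = 0
    init_water_from_data: bool = True
    sanity_range: tuple[float, float] = (-0.1, 1.2)

    @property
    def n_free(self) -> int:
        return sum(p.n_free for p in self.pools)


@dataclass
class FitResult:
    """Fitted pool table plus diagnostics for one spectrum."""

    pools: list[PoolSpec]
    rss: float
    converged: bool
    n_iter: int
    at_bound: dict[str, list[str]] = field(default_factory=dict)
    message: str = ""

    def pool(self, name: str) -> PoolSpec:
        for p in self.pools:
            if p.name == name:
                return p
        raise KeyError(f"no pool named {name!r}; have {[p.name for p in self.pools]}")

    def amplitude(self, name: str) -> float:
        return self.pool(name).amplitude

    def fwhm(self, name: str) -> float:
        return self.pool(name).fwhm


def _pack(pools: list[PoolSpec]):
    """Flatten free parameters -> (x0, lb, ub, layout).

    Layout entries are (pool_index, has_center) in pool order; each pool
    contributes (A, G[, center]).
    """
    x0, lb, ub, layout = [], [], [], []
    for i, p in enumerate(pools):
        has_center = p.center_window > 0
        x0 += [p.amplitude, p.fwhm]
        lb += [p.amplitude_bounds[0], p.fwhm_bounds[0]]
        ub += [p.amplitude_bounds[1], p.fwhm_bounds[1]]
        if has_center:
            x0.append(p.center)
            lb.append(p.center - p.center_window)
            ub.append(p.center + p.center_window)
        layout.append((i, has_center))
    return np.array(x0), np.array(lb), np.array(ub), layout


def _unpack(x: np.ndarray, pools: list[PoolSpec], layout) -> list[PoolSpec]:
    out = []
    k = 0
    for i, has_center in layout:
        p = pools[i]
        a, g = x[k], x[k + 1]
        k += 2
        c = p.center
        if has_center:
            c = x[k]
            k += 1
        out.append(p.with_values(amplitude=min(a, np.nextafter(1.0, 0.0)), fwhm=g, center=c))
    return out


def _model_and_jac(x: np.ndarray, axis: np.ndarray, pools, layout):
    """Return (Z(axis), dZ/dx) for the packed parameter vector."""
    n = axis.size
    z = np.ones(n)
    jac = np.zeros((n, x.size))
    k = 0
    for i, has_center in layout:
        a, g = x[k], x[k + 1]
        c = x[k + 2] if has_center else pools[i].center
        u = (0.5 * g) ** 2
        d = axis - c
        denom = u + d * d
        shape = u / denom
        z -= a * shape
        # residual r = w*(z_obs - Z); dr/dp = +w * dL/dp (handled by caller sign)
        jac[:, k] = shape                                   # dL/dA
        jac[:, k + 1] = a * d * d * (0.5 * g) / denom**2    # dL/dG
        if has_center:
            jac[:, k + 2] = a * u * 2.0 * d / denom**2      # dL/dc
            k += 3
        else:
            k += 2
    return z, jac


def _initial_pools(z: np.ndarray, mask: np.ndarray, config: FitConfig) -> list[PoolSpec]:
    pools = [PoolSpec(**vars(p)) for p in config.pools]
    if config.init_water_from_data:
        for p in pools:
            if p.name == "water":
                a0 = float(np.clip(1.0 - np.min(z[mask]),
                                   p.amplitude_bounds[0] + 1e-6,
                                   p.amplitude_bounds[1] - 1e-6))
                p.amplitude = a0
    return pools


def fit_zspectrum(z: ZSpectrum | np.ndarray, axis: np.ndarray,
                  config: FitConfig | None = None) -> FitResult:
    """Fit the multi-pool Lorentzian model to one Z-spectrum.

    Masked points carry zero weight and never influence the residual.
    Raises :class:`FitError` when fewer than ``n_free + 2`` usable points
    remain or values fall outside the plausibility range; a solver that
    stops without converging still returns its best parameters, flagged
    ``converged=False``.
    """
    if config is None:
        config = FitConfig()
    if not isinstance(z, ZSpectrum):
        z = ZSpectrum(np.asarray(z))
    axis = validate_axis(axis)
    if z.values.shape != axis.shape:
        raise FitError(f"spectrum length {z.values.size} != axis length {axis.size}")
    if z.n_valid < config.n_free + 2:
        raise FitError(
            f"only {z.n_valid} usable points for {config.n_free} free parameters "
            f"(need >= {config.n_free + 2})"
        )
    lo, hi = config.sanity_range
    vals = z.values[z.mask]
    if vals.min() < lo or vals.max() > hi:
        raise FitError(
            f"spectrum values outside plausible range [{lo}, {hi}]: "
            f"min={vals.min():.3g}, max={vals.max():.3g}"
        )

    pools0 = _initial_pools(z.values, z.mask, config)
    x0, lb, ub, layout = _pack(pools0)
    w = z.mask.astype(float)
    obs = np.where(z.mask, z.values, 0.0)

    def resid(x):
        zm, _ = _model_and_jac(x, axis, pools0, layout)
        return w * (obs - zm)

    def jac(x):
        _, j = _model_and_jac(x, axis, pools0, layout)
        return w[:, None] * j

    starts = [x0]
    if config.multi_start > 0:
        rng = np.random.default_rng(config.multi_start_seed)
        span = ub - lb
        for _ in range(config.multi_start):
            starts.append(np.clip(x0 + 0.1 * span * rng.standard_normal(x0.size), lb, ub))

    best = None
    for xs in starts:
        sol = least_squares(resid, xs, jac=jac, bounds=(lb, ub), method="trf",
                            ftol=config.tol, xtol=config.tol, gtol=config.tol,
                            max_nfev=config.max_nfev)
        if best is None or sol.cost < best.cost:
            best = sol

    fitted = _unpack(best.x, pools0, layout)
    at_bound: dict[str, list[str]] = {}
    k = 0
    for i, has_center in layout:
        p = fitted[i]
        names = ["amplitude", "fwhm"] + (["center"] if has_center else [])
        flags = [nm for nm, xi, l, u in
                 zip(names, best.x[k:k + len(names)], lb[k:k + len(names)], ub[k:k + len(names)])
                 if xi - l < 1e-12 or u - xi < 1e-12]
        if flags:
            at_bound[p.name] = flags
        k += len(names)
    return FitResult(
        pools=fitted,
        rss=float(2.0 * best.cost),
        converged=bool(best.status > 0),
        n_iter=int(best.nfev),
        at_bound=at_bound,
        message=best.message,
    )


@dataclass
class FitResultStack:
    """Voxelwise fit results stored as parameter images.

    ``amplitude``/``fwhm`` map pool name -> float image; ``water_center``
    holds the fitted water position; ``fitted`` marks voxels with a result
    and ``converged`` those whose solver converged.
    """

    amplitude: dict[str, np.ndarray]
    fwhm: dict[str, np.ndarray]
    center: dict[str, np.ndarray]
    rss: np.ndarray
    fitted: np.ndarray
    converged: np.ndarray
    n_failed: int = 0

    @property
    def shape(self) -> tuple[int, ...]:
        return self.fitted.shape

    def pool_names(self) -> list[str]:
        return list(self.amplitude)


def fit_stack(z_stack: np.ndarray, axis: np.ndarray, mask: np.ndarray | None = None,
              config: FitConfig | None = None) -> FitResultStack:
    """Fit every unmasked voxel of a stack independently.

    ``z_stack`` has shape ``spatial + (n_offsets,)``; ``mask`` (optional,
    boolean, spatial shape) selects voxels to fit.  NaN spectrum values are
    treated as missing points per voxel.  Voxels whose fit raises are
    skipped and counted, never silently zeroed.
    """
    if config is None:
        config = FitConfig()
    axis = validate_axis(axis)
    z_stack = np.asarray(z_stack, dtype=float)
    if z_stack.shape[-1] != axis.size:
        raise FitError(
            f"stack last dimension {z_stack.shape[-1]} != axis length {axis.size}"
        )
    spatial = z_stack.shape[:-1]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != spatial:
        raise FitError(f"mask shape {mask.shape} != stack spatial shape {spatial}")

    names = [p.name for p in config.pools]
    amp = {n: np.full(spatial, np.nan) for n in names}
    fwhm = {n: np.full(spatial, np.nan) for n in names}
    cen = {n: np.full(spatial, np.nan) for n in names}
    rss = np.full(spatial, np.nan)
    fitted = np.zeros(spatial, dtype=bool)
    converged = np.zeros(spatial, dtype=bool)

    idxs = np.argwhere(mask)
    if idxs.size == 0:
        raise FitError("all voxels are masked; nothing to fit")
    n_failed = 0
    for idx in map(tuple, idxs):
        try:
            res = fit_zspectrum(z_stack[idx], axis, config)
        except FitError as exc:
            n_failed += 1
            log.debug("voxel %s skipped: %s", idx, exc)
            continue
        fitted[idx] = True
        converged[idx] = res.converged
        rss[idx] = res.rss
        for p in res.pools:
            amp[p.name][idx] = p.amplitude
            fwhm[p.name][idx] = p.fwhm
            cen[p.name][idx] = p.center
    if not fitted.any():
        raise FitError("every voxel failed to fit")
    if n_failed:
        log.warning("fit_stack: %d voxel(s) skipped", n_failed)
    return FitResultStack(amplitude=amp, fwhm=fwhm, center=cen, rss=rss,
                          fitted=fitted, converged=converged, n_failed=n_failed)
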