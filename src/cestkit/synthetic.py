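"""Synthetic CEST phantoms with known ground truth.

No imaging data accompany the study design this pipeline targets, so this
module generates everything downstream stages consume: per-voxel Z-spectrum
stacks built from the five-pool Lorentzian forward model, a paired
low-power WASSR stack sharing the same smooth B0 field, an integer ROI
label map over five named brain regions, and a subject/arm assignment
table.  Ground truth (per-voxel amplitudes, B0 field, region-level
amplitude table) is recorded for recovery tests.

Study conditions follow the experimental design being emulated: four arms
(pre-infection baseline, 6 weeks post-infection, and 12 weeks
post-infection under vehicle or antiretroviral treatment) with 14/14/5/4
subjects, arm-level amplitude effects on the solute pools, 5% between-
subject coefficient of variation, and additive Gaussian noise on the
normalized signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .axis import default_axis, default_wassr_axis, validate_axis
from .lorentzfit import ZSpectrum, lorentzian
from .pools import POOL_CENTERS, POOL_NAMES, PoolSpec

__all__ = [
    "ARM_NAMES",
    "REGION_NAMES",
    "PhantomConfigError",
    "PhantomConfig",
    "GroundTruth",
    "PhantomDataset",
    "simulate_zspectrum",
    "simulate_wassr",
    "simulate_phantom",
    "simulate_contrast_table",
    "default_region_layout",
    "default_pool_truth",
    "default_demo_config",
]

ARM_NAMES: tuple[str, ...] = ("baseline", "wk6", "wk12_vehicle", "wk12_art")
REGION_NAMES: tuple[str, ...] = (
    "cortex", "hippocampus", "hypothalamus", "piriform_cortex", "thalamus",
)

#: baseline pool amplitudes; sum 0.95 keeps the noiseless spectrum positive
BASE_AMPLITUDES: dict[str, float] = {
    "water": 0.72, "mt": 0.08, "creatine": 0.04, "glutamate": 0.05, "noe": 0.06,
}
#: pool linewidths (FWHM, ppm)
BASE_LINEWIDTHS: dict[str, float] = {
    "water": 1.4, "mt": 3.0, "creatine": 1.0, "glutamate": 1.2, "noe": 2.5,
}


class PhantomConfigError(ValueError):
    """Raised for inconsistent phantom configurations."""


def simulate_zspectrum(pools: list[PoolSpec], axis: np.ndarray, b0_offset: float = 0.0,
                       noise_sigma: float = 0.0,
                       seed: int | np.random.Generator | None = None) -> ZSpectrum:
    """Forward-simulate one Z-spectrum: ``Z(dw) = 1 - sum_i L_i(dw - b0)``.

    Noise is additive Gaussian on the normalized signal (Z-spectra are
    high-SNR magnitude ratios, so Rician bias is negligible and not
    modeled).  Amplitudes must sum below 1 for a valid pool system.
    """
    axis = validate_axis(axis)
    total = sum(p.amplitude for p in pools)
    if total >= 1.0:
        raise PhantomConfigError(
            f"invalid pool system: amplitudes sum to {total:.3f} >= 1"
        )
    if noise_sigma < 0:
        raise PhantomConfigError(f"noise_sigma must be >= 0, got {noise_sigma}")
    z = np.ones_like(axis)
    for p in pools:
        z -= lorentzian(axis - b0_offset, p.amplitude, p.center, p.fwhm)
    if noise_sigma > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        z = z + rng.normal(0.0, noise_sigma, size=z.shape)
    return ZSpectrum(z)


def simulate_wassr(b0_offset: float, axis: np.ndarray | None = None,
                   water_linewidth: float = 0.3, water_amplitude: float = 0.9,
                   noise_sigma: float = 0.0,
                   seed: int | np.random.Generator | None = None) -> ZSpectrum:
    """Water-only spectrum whose noiseless minimum sits at ``b0_offset``.

    Defaults model the conventional WASSR scan: narrow ±1 ppm axis at
    0.05 ppm steps and a narrow direct-saturation line (long low-power
    saturation still saturates water nearly completely on resonance).
    """
    if water_linewidth <= 0:
        raise PhantomConfigError("water_linewidth must be > 0")
    if axis is None:
        axis = default_wassr_axis()
    pool = PoolSpec("water", 0.0, water_amplitude, water_linewidth,
                    fwhm_bounds=(0.05, 5.0))
    return simulate_zspectrum([pool], axis, b0_offset=b0_offset,
                              noise_sigma=noise_sigma, seed=seed)


def default_region_layout(grid_shape: tuple[int, int] = (64, 64),
                          block: tuple[int, int] = (10, 10)) -> dict[str, list[tuple[int, int]]]:
    """Five disjoint rectangular regions spread over the grid.

    Anatomical fidelity is not a goal — what matters downstream is the
    label structure, so simple blocks placed clear of each other suffice.
    """
    nx, ny = grid_shape
    bx, by = block
    # anchor fractions chosen to keep blocks disjoint for any grid >= 4x the block
    anchors = [(0.10, 0.10), (0.10, 0.60), (0.45, 0.35), (0.75, 0.10), (0.75, 0.60)]
    layout: dict[str, list[tuple[int, int]]] = {}
    for name, (fx, fy) in zip(REGION_NAMES, anchors):
        x0, y0 = int(fx * nx), int(fy * ny)
        if x0 + bx > nx or y0 + by > ny:
            raise PhantomConfigError(
                f"grid {grid_shape} too small for {block} blocks"
            )
        layout[name] = [(i, j) for i in range(x0, x0 + bx) for j in range(y0, y0 + by)]
    return layout


def default_pool_truth(arms: tuple[str, ...] = ARM_NAMES,
                       regions: tuple[str, ...] = REGION_NAMES,
                       ) -> dict[tuple[str, str, str], float]:
    """Arm/region amplitude truth emulating the study's effect structure.

    Relative to baseline: at 6 weeks creatine drops in cortex and
    hippocampus and the NOE rises in cortex and thalamus; by 12 weeks
    untreated, glutamate drops 20% in cortex/hippocampus/piriform cortex
    (10% elsewhere), creatine drops 20% in four regions, and the NOE is
    elevated.  The treated arm restores glutamate and creatine to baseline
    while the NOE stays elevated.
    """
    glu_drop = {"cortex": 0.80, "hippocampus": 0.80, "piriform_cortex": 0.80,
                "hypothalamus": 0.90, "thalamus": 0.90}
    cr_drop = {"cortex": 0.80, "hippocampus": 0.80, "piriform_cortex": 0.80,
               "thalamus": 0.80, "hypothalamus": 0.90}
    cr_drop6 = {"cortex": 0.85, "hippocampus": 0.85}
    noe_up = {"cortex": 1.20, "thalamus": 1.20, "hippocampus": 1.10}
    noe_up6 = {"cortex": 1.15, "thalamus": 1.15}

    truth: dict[tuple[str, str, str], float] = {}
    for arm in arms:
        for region in regions:
            for pool in POOL_NAMES:
                a = BASE_AMPLITUDES[pool]
                if pool == "glutamate" and arm == "wk12_vehicle":
                    a *= glu_drop.get(region, 1.0)
                elif pool == "creatine":
                    if arm == "wk6":
                        a *= cr_drop6.get(region, 1.0)
                    elif arm == "wk12_vehicle":
                        a *= cr_drop.get(region, 1.0)
                elif pool == "noe":
                    if arm == "wk6":
                        a *= noe_up6.get(region, 1.0)
                    elif arm in ("wk12_vehicle", "wk12_art"):
                        a *= noe_up.get(region, 1.0)
                truth[(arm, region, pool)] = a
    return truth


@dataclass
class PhantomConfig:
    """Full description of one synthetic study.

    ``pool_truth`` maps ``(arm, region, pool)`` to a Lorentzian amplitude;
    ``b0_coeffs`` are the six coefficients ``(c0, cx, cy, cxy, cxx, cyy)``
    of a quadratic field in grid coordinates normalized to [-1, 1], bounded
    by ``b0_bound`` ppm.  Between-subject variation is Gaussian jitter on
    region amplitudes with coefficient of variation ``subject_cv``.
    """

    grid_shape: tuple[int, int] = (64, 64)
    region_layout: dict[str, list[tuple[int, int]]] = field(default_factory=default_region_layout)
    arms: tuple[str, ...] = ARM_NAMES
    n_subjects_per_arm: dict[str, int] = field(
        default_factory=lambda: {"baseline": 14, "wk6": 14, "wk12_vehicle": 5, "wk12_art": 4})
    pool_truth: dict[tuple[str, str, str], float] = field(default_factory=default_pool_truth)
    linewidths: dict[str, float] = field(default_factory=lambda: dict(BASE_LINEWIDTHS))
    b0_coeffs: tuple[float, ...] = (0.05, 0.10, -0.08, 0.06, -0.10, 0.07)
    b0_bound: float = 0.5
    noise_sigma: float = 0.005
    subject_cv: float = 0.05
    wassr_linewidth: float = 0.3
    wassr_amplitude: float = 0.9
    wassr_noise_sigma: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        nx, ny = self.grid_shape
        if nx < 1 or ny < 1:
            raise PhantomConfigError(f"bad grid_shape {self.grid_shape}")
        seen: set[tuple[int, int]] = set()
        for name, vox in self.region_layout.items():
            for (i, j) in vox:
                if not (0 <= i < nx and 0 <= j < ny):
                    raise PhantomConfigError(
                        f"region {name!r} voxel {(i, j)} outside grid {self.grid_shape}"
                    )
                if (i, j) in seen:
                    raise PhantomConfigError(f"region layouts overlap at {(i, j)}")
                seen.add((i, j))
        for arm in self.arms:
            n = self.n_subjects_per_arm.get(arm, 0)
            if n < 1:
                raise PhantomConfigError(f"arm {arm!r} needs >= 1 subject, got {n}")
            for region in self.region_layout:
                amps = []
                for pool in POOL_NAMES:
                    key = (arm, region, pool)
                    if key not in self.pool_truth:
                        raise PhantomConfigError(f"pool_truth missing {key}")
                    a = self.pool_truth[key]
                    if not (0 <= a < 1):
                        raise PhantomConfigError(f"amplitude {key} = {a} outside [0, 1)")
                    amps.append(a)
                if sum(amps) >= 1.0:
                    raise PhantomConfigError(
                        f"amplitudes for ({arm}, {region}) sum to {sum(amps):.3f} >= 1"
                    )
        for pool, g in self.linewidths.items():
            if g <= 0:
                raise PhantomConfigError(f"linewidth for {pool!r} must be > 0")
        if self.noise_sigma < 0 or self.wassr_noise_sigma < 0:
            raise PhantomConfigError("noise sigma must be >= 0")
        if max(abs(v) for v in self._b0_field().ravel()) > self.b0_bound + 1e-12:
            raise PhantomConfigError(
                f"B0 field exceeds ±{self.b0_bound} ppm bound"
            )

    def _b0_field(self) -> np.ndarray:
        nx, ny = self.grid_shape
        u = np.linspace(-1.0, 1.0, nx)[:, None] if nx > 1 else np.zeros((1, 1))
        v = np.linspace(-1.0, 1.0, ny)[None, :] if ny > 1 else np.zeros((1, 1))
        c0, cx, cy, cxy, cxx, cyy = self.b0_coeffs
        return (c0 + cx * u + cy * v + cxy * u * v + cxx * u**2 + cyy * v**2
                ) * np.ones((nx, ny))

    def label_map(self) -> np.ndarray:
        labels = np.zeros(self.grid_shape, dtype=np.int16)
        for k, name in enumerate(self.region_layout, start=1):
            for (i, j) in self.region_layout[name]:
                labels[i, j] = k
        return labels

    def region_ids(self) -> dict[int, str]:
        return {k: name for k, name in enumerate(self.region_layout, start=1)}


@dataclass
class GroundTruth:
    """Everything the generator knows: the oracle for recovery tests."""

    amplitudes: np.ndarray            # (n_subjects, nx, ny, n_pools)
    pool_names: tuple[str, ...]
    b0: np.ndarray                    # (nx, ny) ppm
    labels: np.ndarray                # (nx, ny) int, 0 = background
    region_ids: dict[int, str]
    subjects: pd.DataFrame            # columns: subject, arm
    region_amplitudes: pd.DataFrame   # columns: subject, arm, region, pool, amplitude


@dataclass
class PhantomDataset:
    """One simulated study: stacks, axes, labels, metadata and truth."""

    z: np.ndarray          # (n_subjects, nx, ny, n_offsets)
    wassr: np.ndarray      # (n_subjects, nx, ny, n_wassr_offsets)
    axis: np.ndarray
    wassr_axis: np.ndarray
    labels: np.ndarray
    region_ids: dict[int, str]
    subjects: pd.DataFrame
    truth: GroundTruth
    config: PhantomConfig


def _region_spectra(amps: np.ndarray, fwhms: np.ndarray, centers: np.ndarray,
                    axis: np.ndarray, b0: np.ndarray) -> np.ndarray:
    """Vectorized forward model for many voxels sharing the pool table.

    ``amps``: (n_vox, n_pools); ``b0``: (n_vox,).  Returns (n_vox, n_axis).
    """
    d = axis[None, :] - b0[:, None]               # (n_vox, n_axis)
    z = np.ones((b0.size, axis.size))
    for p in range(centers.size):
        hw2 = (0.5 * fwhms[p]) ** 2
        z -= amps[:, p:p + 1] * hw2 / (hw2 + (d - centers[p]) ** 2)
    return z


def simulate_phantom(config: PhantomConfig | None = None) -> PhantomDataset:
    """Simulate the full study: all subjects, both stacks, ground truth.

    Deterministic: identical config (including seed) gives bit-identical
    arrays.  Background voxels (label 0) hold a pure-noise signal around 1
    and are excluded from all downstream quantification by the label map.
    """
    if config is None:
        config = default_demo_config()
    config.validate()
    rng = np.random.default_rng(config.seed)
    axis = default_axis()
    wassr_axis = default_wassr_axis()
    nx, ny = config.grid_shape
    labels = config.label_map()
    b0 = config._b0_field()
    fwhms = np.array([config.linewidths[p] for p in POOL_NAMES])
    centers = np.array([POOL_CENTERS[p] for p in POOL_NAMES])

    subject_rows, ra_rows = [], []
    n_total = sum(config.n_subjects_per_arm[a] for a in config.arms)
    z = np.empty((n_total, nx, ny, axis.size))
    wassr = np.empty((n_total, nx, ny, wassr_axis.size))
    amp_truth = np.zeros((n_total, nx, ny, len(POOL_NAMES)))

    s = 0
    for arm in config.arms:
        for k in range(config.n_subjects_per_arm[arm]):
            sid = f"{arm}_{k + 1:02d}"
            subject_rows.append({"subject": sid, "arm": arm})
            # start from noise-only background
            z[s] = 1.0 + rng.normal(0.0, config.noise_sigma, size=(nx, ny, axis.size)) \
                if config.noise_sigma > 0 else 1.0
            wassr[s] = 1.0 + rng.normal(0.0, config.wassr_noise_sigma,
                                        size=(nx, ny, wassr_axis.size)) \
                if config.wassr_noise_sigma > 0 else 1.0
            for region, vox in config.region_layout.items():
                base = np.array([config.pool_truth[(arm, region, p)] for p in POOL_NAMES])
                jit = base * (1.0 + config.subject_cv * rng.standard_normal(base.size))
                jit = np.clip(jit, 0.0, None)
                total = jit.sum()
                if total >= 1.0:       # rare tail event; rescale to stay valid
                    jit *= 0.999 / total
                for p, pool in enumerate(POOL_NAMES):
                    ra_rows.append({"subject": sid, "arm": arm, "region": region,
                                    "pool": pool, "amplitude": jit[p]})
                ij = np.array(vox)
                vb0 = b0[ij[:, 0], ij[:, 1]]
                clean = _region_spectra(np.tile(jit, (len(vox), 1)), fwhms, centers,
                                        axis, vb0)
                noise = rng.normal(0.0, config.noise_sigma, size=clean.shape) \
                    if config.noise_sigma > 0 else 0.0
                z[s, ij[:, 0], ij[:, 1], :] = clean + noise
                amp_truth[s, ij[:, 0], ij[:, 1], :] = jit
                # WASSR water line shares the same field
                hw2 = (0.5 * config.wassr_linewidth) ** 2
                dw = wassr_axis[None, :] - vb0[:, None]
                wline = 1.0 - config.wassr_amplitude * hw2 / (hw2 + dw**2)
                wnoise = rng.normal(0.0, config.wassr_noise_sigma, size=wline.shape) \
                    if config.wassr_noise_sigma > 0 else 0.0
                wassr[s, ij[:, 0], ij[:, 1], :] = wline + wnoise
            s += 1

    subjects = pd.DataFrame(subject_rows)
    truth = GroundTruth(
        amplitudes=amp_truth, pool_names=POOL_NAMES, b0=b0, labels=labels,
        region_ids=config.region_ids(), subjects=subjects,
        region_amplitudes=pd.DataFrame(ra_rows),
    )
    return PhantomDataset(z=z, wassr=wassr, axis=axis, wassr_axis=wassr_axis,
                          labels=labels, region_ids=config.region_ids(),
                          subjects=subjects, truth=truth, config=config)


def simulate_contrast_table(config: PhantomConfig | None = None,
                            seed: int | None = None,
                            pools: tuple[str, ...] = ("glutamate", "creatine", "noe"),
                            ) -> pd.DataFrame:
    """Draw a per-subject region contrast table directly from the truth.

    Each (subject, region, pool) contrast is the ground-truth Lorentzian
    area ``A * pi * Gamma / 2`` under the arm/region amplitude, jittered by
    the between-subject coefficient of variation.  This is the region-level
    marginal the full imaging pipeline estimates; drawing it directly makes
    large statistical calibration studies (thousands of replicate tables)
    cheap while preserving the group structure, sample sizes and variance
    the study conditions define.
    """
    if config is None:
        config = default_demo_config()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    for arm in config.arms:
        for k in range(config.n_subjects_per_arm[arm]):
            sid = f"{arm}_{k + 1:02d}"
            for region in config.region_layout:
                for pool in pools:
                    a = config.pool_truth[(arm, region, pool)]
                    g = config.linewidths[pool]
                    val = a * (1.0 + config.subject_cv * rng.standard_normal())
                    rows.append({"subject": sid, "arm": arm, "region": region,
                                 "pool": pool,
                                 "contrast": max(val, 0.0) * np.pi * g / 2.0})
    return pd.DataFrame(rows)


def default_demo_config(seed: int = 0) -> PhantomConfig:
    """Demo study at a grid size sized for desktop end-to-end runs.

    Keeps the study's arm structure, sample sizes, effect sizes, 5% CV and
    noise level; uses a 32x32 grid with 6x6 regions so a full voxelwise run
    (B0 map, per-voxel five-pool fits, contrast maps, statistics) finishes
    in minutes on one core.
    """
    grid = (32, 32)
    return PhantomConfig(
        grid_shape=grid,
        region_layout=default_region_layout(grid, block=(6, 6)),
        seed=seed,
    )
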