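"""Pool definitions for multi-pool Lorentzian Z-spectrum models.

The five-pool model resolves the Z-spectrum into direct water saturation
(0 ppm), semi-solid magnetization transfer (MT, fitted at -1 ppm), creatine
(2 ppm), glutamate (3 ppm) and the relayed nuclear Overhauser effect
(NOE, -3.5 ppm).  Each pool is an amplitude/FWHM Lorentzian dip.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["PoolSpec", "POOL_NAMES", "POOL_CENTERS", "default_pools", "water_solute_pools"]

#: canonical pool order used throughout the package
POOL_NAMES: tuple[str, ...] = ("water", "mt", "creatine", "glutamate", "noe")

#: fixed resonance offsets (ppm from water)
POOL_CENTERS: dict[str, float] = {
    "water": 0.0,
    "mt": -1.0,
    "creatine": 2.0,
    "glutamate": 3.0,
    "noe": -3.5,
}

#: default FWHM bounds in ppm; MT is broad by nature
_FWHM_BOUNDS: dict[str, tuple[float, float]] = {
    "water": (0.3, 4.0),
    "mt": (1.0, 20.0),
    "creatine": (0.3, 3.0),
    "glutamate": (0.3, 4.0),
    "noe": (0.5, 6.0),
}


@dataclass
class PoolSpec:
    """One Lorentzian pool: initial values, bounds, and which parameters float.

    Parameters
    ----------
    name
        Pool label (free-form; the five canonical names carry defaults).
    center
        Resonance offset delta in ppm.  Fixed during fitting unless
        ``center_window > 0``, in which case it floats within
        ``center ± center_window`` (used for water to absorb residual B0).
    amplitude, fwhm
        Initial amplitude A (dimensionless, in [0, 1)) and linewidth
        Gamma (ppm, FWHM).
    """

    name: str
    center: float
    amplitude: float = 0.02
    fwhm: float = 1.0
    amplitude_bounds: tuple[float, float] = (0.0, 1.0)
    fwhm_bounds: tuple[float, float] = (0.1, 10.0)
    center_window: float = 0.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"pool {self.name!r}: fwhm must be > 0, got {self.fwhm}")
        lo, hi = self.fwhm_bounds
        if lo <= 0 or hi <= lo:
            raise ValueError(f"pool {self.name!r}: invalid fwhm bounds {self.fwhm_bounds}")
        if not (0 <= self.amplitude < 1):
            raise ValueError(
                f"pool {self.name!r}: amplitude must be in [0, 1), got {self.amplitude}"
            )

    @property
    def n_free(self) -> int:
        return 3 if self.center_window > 0 else 2

    def with_values(self, amplitude: float | None = None, fwhm: float | None = None,
                    center: float | None = None) -> "PoolSpec":
        kw = {}
        if amplitude is not None:
            kw["amplitude"] = amplitude
        if fwhm is not None:
            kw["fwhm"] = fwhm
        if center is not None:
            kw["center"] = center
        return replace(self, **kw)


def _mid(bounds: tuple[float, float]) -> float:
    return 0.5 * (bounds[0] + bounds[1])


def default_pools() -> list[PoolSpec]:
    """The five-pool table with standard 7T priors.

    Centers are fixed for the solute/MT/NOE pools (the usual stabilizer for
    five-pool fits); the water center floats within ±0.2 ppm to absorb
    residual B0 error.  Linewidth initial values sit at the midpoint of
    their bounds; solute amplitudes start at 0.02 and the water amplitude
    is re-initialized from the data by the fitter.
    """
    pools = []
    for name in POOL_NAMES:
        b = _FWHM_BOUNDS[name]
        pools.append(
            PoolSpec(
                name=name,
                center=POOL_CENTERS[name],
                amplitude=0.02,
                fwhm=_mid(b),
                fwhm_bounds=b,
                center_window=0.2 if name == "water" else 0.0,
            )
        )
    return pools


def water_solute_pools(solute_center: float, solute_fwhm_bounds=(0.2, 3.0)) -> list[PoolSpec]:
    """Two-pool table (water + one solute) for simple phantoms and oracles."""
    wb = _FWHM_BOUNDS["water"]
    return [
        PoolSpec("water", 0.0, 0.5, _mid(wb), fwhm_bounds=wb, center_window=0.2),
        PoolSpec(
            "solute",
            solute_center,
            0.01,
            _mid(solute_fwhm_bounds),
            fwhm_bounds=solute_fwhm_bounds,
        ),
    ]
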