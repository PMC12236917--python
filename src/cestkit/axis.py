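"""Saturation-offset frequency axes.

A CEST acquisition samples the Z-spectrum at a list of saturation offsets
(ppm relative to water).  Preclinical protocols commonly use non-uniform
sampling: coarse steps in the outer wings and fine steps across the window
containing the solute resonances.  The default scheme here is 0.2 ppm steps
on [-5, -4] and [4, 5] ppm and 0.1 ppm steps on [-4, 4] ppm, which yields
91 unique offsets spanning -5 to +5 ppm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Segment",
    "AxisError",
    "build_offset_axis",
    "default_scheme",
    "default_axis",
    "default_wassr_axis",
]

#: decimal places used to snap offsets before de-duplication
_DECIMALS = 9


class AxisError(ValueError):
    """Raised for inconsistent offset-scheme specifications."""


@dataclass(frozen=True)
class Segment:
    """One contiguous arithmetic block of saturation offsets.

    ``start``/``stop`` are in ppm, ``step`` is the (positive) increment.
    ``stop - start`` must be an integer multiple of ``step``.
    """

    start: float
    stop: float
    step: float

    def points(self) -> np.ndarray:
        if self.step <= 0:
            raise AxisError(f"segment step must be positive, got {self.step}")
        if self.stop <= self.start:
            raise AxisError(
                f"segment must run forward: start={self.start}, stop={self.stop}"
            )
        n = (self.stop - self.start) / self.step
        n_int = round(n)
        if abs(n - n_int) > 1e-9:
            raise AxisError(
                f"segment [{self.start}, {self.stop}] is not an integer number "
                f"of steps of {self.step}"
            )
        return np.round(self.start + self.step * np.arange(n_int + 1), _DECIMALS)


def default_scheme() -> list[Segment]:
    """The acquisition scheme of the reference protocol: coarse wings, fine core."""
    return [
        Segment(-5.0, -4.0, 0.2),
        Segment(-4.0, 4.0, 0.1),
        Segment(4.0, 5.0, 0.2),
    ]


def build_offset_axis(scheme: list[Segment] | None = None) -> np.ndarray:
    """Build a strictly increasing, de-duplicated offset axis from a scheme.

    Parameters
    ----------
    scheme
        Ordered, contiguous segments.  Adjacent segments may share an
        endpoint (counted once).  ``None`` uses :func:`default_scheme`.

    Returns
    -------
    numpy.ndarray
        1-D array of offsets in ppm, strictly increasing.
    """
    if scheme is None:
        scheme = default_scheme()
    if not scheme:
        raise AxisError("offset scheme is empty")
    segs = [s if isinstance(s, Segment) else Segment(*s) for s in scheme]
    for prev, cur in zip(segs, segs[1:]):
        if cur.start < prev.stop - 1e-9:
            # overlap is only legal if the shared region is step-consistent;
            # simplest sound rule: forbid interior overlap outright
            raise AxisError(
                f"segments overlap: [{prev.start}, {prev.stop}] and "
                f"[{cur.start}, {cur.stop}]"
            )
    points = np.concatenate([s.points() for s in segs])
    axis = np.unique(points)
    if not np.all(np.diff(axis) > 0):
        raise AxisError("constructed axis is not strictly increasing")
    return axis


def default_axis() -> np.ndarray:
    """The 91-point acquisition axis from -5 to +5 ppm."""
    return build_offset_axis(default_scheme())


def default_wassr_axis(half_width: float = 1.0, step: float = 0.05) -> np.ndarray:
    """Narrow, uniform axis for the low-power water-only (WASSR) scan.

    The reference protocol does not document its WASSR sampling; a ±1 ppm
    window at 0.05 ppm steps is the conventional choice and comfortably
    brackets B0 offsets up to ±0.5 ppm.
    """
    return build_offset_axis([Segment(-half_width, half_width, step)])


def validate_axis(axis: np.ndarray, min_points: int = 2) -> np.ndarray:
    """Return ``axis`` as a float array after sanity checks."""
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < min_points:
        raise AxisError(f"axis must be 1-D with >= {min_points} points")
    if not np.all(np.isfinite(axis)):
        raise AxisError("axis contains non-finite offsets")
    if not np.all(np.diff(axis) > 0):
        raise AxisError("axis must be strictly increasing")
    return axis
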