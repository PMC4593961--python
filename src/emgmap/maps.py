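"""RMS activation maps and their two spatial statistics.

An :class:`RmsMap` arranges per-channel baseline-corrected RMS values on
the electrode grid.  Two scalar statistics summarize it:

* the **centroid** — the RMS-weighted mean of the channel coordinates,

  ``cx = sum_ij(RMS_ij * x_i) / sum_ij(RMS_ij)`` and likewise for ``cy``;

* the **SSD** — a normalized sum of squared differences between two
  max-normalized maps,

  ``SSD = 100 * sum_ij(nA - nB)^2 / sum_ij(nA^2 + nB^2)``,

  which is 0 for identical maps and 100 for maps with disjoint support.
  The denominator ``sum(nA^2 + nB^2)`` is the unique simple quadratic
  normalization with both of those boundary behaviours; it is isolated
  in :func:`ssd_denominator` so alternatives can be swapped in and
  compared.

Both statistics always use the un-interpolated grid values;
:func:`interpolate_for_display` exists purely for visualization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .exceptions import DegenerateMapError, InvalidInputError
from .grid import ElectrodeGrid

__all__ = [
    "RmsMap",
    "NormalizedMap",
    "Centroid",
    "SsdResult",
    "build_map",
    "centroid",
    "normalize_map",
    "ssd",
    "ssd_denominator",
    "interpolate_for_display",
]


@dataclass(frozen=True)
class RmsMap:
    """Non-negative RMS values arranged on the grid.

    ``values[row, col]`` corresponds to the electrode at that grid
    position; shape must match the grid.
    """

    values: np.ndarray
    grid: ElectrodeGrid
    condition: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.shape:
            raise InvalidInputError(
                f"map shape {v.shape} does not match grid shape {self.grid.shape}"
            )
        if np.any(v < 0):
            raise InvalidInputError(
                "RmsMap values must be non-negative (apply baseline flooring upstream)"
            )
        object.__setattr__(self, "values", v)

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class NormalizedMap:
    """A map divided by its own maximum (max element == 1).

    ``degenerate`` flags an all-zero source map, which cannot be
    normalized and is excluded from SSD computations.
    """

    values: np.ndarray
    grid: ElectrodeGrid
    condition: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class Centroid:
    """Activation barycenter: (% circumference, % forearm length)."""

    cx: float
    cy: float


@dataclass(frozen=True)
class SsdResult:
    """Normalized map-difference percentage between two conditions."""

    ssd_percent: float
    condition_pair: tuple[str, str]


def build_map(per_channel_rms: np.ndarray, grid: ElectrodeGrid, condition: str = "") -> RmsMap:
    """Arrange a per-channel RMS vector into a grid map (row-major)."""
    v = np.asarray(per_channel_rms, dtype=float)
    if v.ndim != 1 or v.size != grid.n_channels:
        raise InvalidInputError(
            f"expected a flat vector of {grid.n_channels} channel values, got shape {v.shape}"
        )
    return RmsMap(values=v.reshape(grid.shape), grid=grid, condition=condition)


def centroid(rms_map: RmsMap) -> Centroid:
    """RMS-weighted mean of the channel coordinates.

    Invariant to global scaling of the map.  Raises
    :class:`DegenerateMapError` for an all-zero map, where the centroid
    is undefined.
    """
    w = rms_map.values
    total = w.sum()
    if total <= 0:
        raise DegenerateMapError("centroid of an all-zero map is undefined")
    x_mesh, y_mesh = rms_map.grid.coordinate_mesh()
    cx = float((w * x_mesh).sum() / total)
    cy = float((w * y_mesh).sum() / total)
    return Centroid(cx=cx, cy=cy)


def normalize_map(rms_map: RmsMap) -> NormalizedMap:
    """Divide by the map's own maximum so the peak equals 1.

    An all-zero map cannot be normalized; it is returned unchanged with
    ``degenerate=True`` and must be excluded from SSD.
    """
    peak = rms_map.values.max() if rms_map.values.size else 0.0
    if peak <= 0:
        return NormalizedMap(
            values=np.zeros_like(rms_map.values),
            grid=rms_map.grid,
            condition=rms_map.condition,
            degenerate=True,
        )
    return NormalizedMap(
        values=rms_map.values / peak,
        grid=rms_map.grid,
        condition=rms_map.condition,
        degenerate=False,
    )


def ssd_denominator(a: np.ndarray, b: np.ndarray, variant: str = "sum_of_squares") -> float:
    """Normalization term of the SSD statistic.

    ``"sum_of_squares"`` (default) uses ``sum(a^2 + b^2)``, giving 0 for
    identical maps and exactly 100 for disjoint-support maps.  A custom
    callable ``f(a, b) -> float`` may be registered by passing it as
    ``variant`` to :func:`ssd` for sensitivity analyses.
    """
    if variant == "sum_of_squares":
        # summed elementwise in the same order as the numerator so that
        # disjoint-support maps give exactly 100
        return float(np.sum(np.square(a) + np.square(b)))
    raise InvalidInputError(f"unknown SSD denominator variant {variant!r}")


def ssd(
    a: NormalizedMap,
    b: NormalizedMap,
    denominator: str | Callable[[np.ndarray, np.ndarray], float] = "sum_of_squares",
) -> SsdResult:
    """Normalized sum-of-squared-differences between two maps, in %.

    Symmetric in its arguments; 0 iff the maps are identical; bounded by
    100 for non-negative maps (the cross term ``sum(a * b) >= 0``), with
    100 attained exactly when the maps' supports are disjoint.

    Raises
    ------
    InvalidInputError
        On shape mismatch.
    DegenerateMapError
        If either input is a flagged all-zero map.
    """
    if a.values.shape != b.values.shape:
        raise InvalidInputError(
            f"map shapes differ: {a.values.shape} vs {b.values.shape}"
        )
    if a.degenerate or b.degenerate:
        raise DegenerateMapError("SSD is undefined for an all-zero (degenerate) map")
    num = float(np.sum(np.square(a.values - b.values)))
    if callable(denominator):
        den = float(denominator(a.values, b.values))
    else:
        den = ssd_denominator(a.values, b.values, denominator)
    if den <= 0:
        raise DegenerateMapError("SSD denominator is zero")
    return SsdResult(
        ssd_percent=100.0 * (num / den),
        condition_pair=(a.condition, b.condition),
    )


def interpolate_for_display(rms_map: RmsMap, factor: int = 6) -> np.ndarray:
    """Bilinear upsampling on the relative-coordinate lattice.

    Produces a ``((n_rows - 1) * factor + 1, (n_cols - 1) * factor + 1)``
    dense matrix for visualization only — centroid and SSD always use
    the original un-interpolated values.  Original lattice points are
    reproduced exactly (every ``factor``-th sample).
    """
    if factor < 1:
        raise InvalidInputError("interpolation factor must be >= 1")
    if factor == 1:
        return rms_map.values.copy()
    grid = rms_map.grid
    if grid.n_rows == 1 and grid.n_cols == 1:
        return rms_map.values.copy()
    ys = np.asarray(grid.y_per_row)
    xs = np.asarray(grid.x_per_col)
    dense_y = np.linspace(ys[0], ys[-1], (grid.n_rows - 1) * factor + 1) if grid.n_rows > 1 else ys
    dense_x = np.linspace(xs[0], xs[-1], (grid.n_cols - 1) * factor + 1) if grid.n_cols > 1 else xs
    if grid.n_rows == 1:
        return np.interp(dense_x, xs, rms_map.values[0])[np.newaxis, :]
    if grid.n_cols == 1:
        return np.interp(dense_y, ys, rms_map.values[:, 0])[:, np.newaxis]
    interp = RegularGridInterpolator((ys, xs), rms_map.values, method="linear")
    yy, xx = np.meshgrid(dense_y, dense_x, indexing="ij")
    return interp(np.stack([yy.ravel(), xx.ravel()], axis=1)).reshape(yy.shape)
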