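"""Electrode-grid geometry in relative forearm coordinates.

Coordinate conventions (fixed throughout the package):

* ``y`` is % of forearm length, 0% at the proximal landmark (olecranon)
  and 100% at the distal landmark (ulnar styloid).  Row 1 is the most
  proximal row; rows sit at the centers of equal-length segments, so row
  ``r`` of ``R`` rows lies at ``y = 100 * (r - 0.5) / R``.
* ``x`` is % of forearm circumference on a linear [0, 100) axis with the
  seam (0% == 100%) at the medial forearm.  No circular arithmetic is
  applied anywhere downstream: activation of interest sits mid-axis,
  far from the seam, and the centroid is defined on the linear axis.
* Channels are numbered row-major: channel ``r * n_cols + c`` is row
  ``r``, column ``c`` (both 0-based).  Channel names are ``R{row}C{col}``
  with 1-based row/col.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidConfigurationError

__all__ = ["ForearmGeometry", "ElectrodeGrid", "build_grid", "channel_coordinates"]

#: Width (in %) treated as covering the full circumference, where the
#: last electrode must not coincide with the first (0% == 100% seam).
_FULL_SPAN = 100.0


@dataclass(frozen=True)
class ForearmGeometry:
    """Physical forearm dimensions used to place the grid.

    Parameters
    ----------
    length_mm
        Proximal-to-distal span (olecranon to ulnar styloid), mm.
    circumference_mm_by_row
        Forearm circumference at each electrode row, proximal first, mm.
        Typically non-increasing proximal to distal, but not required.
    """

    length_mm: float
    circumference_mm_by_row: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise InvalidConfigurationError("forearm length must be positive")
        circ = tuple(float(c) for c in self.circumference_mm_by_row)
        if len(circ) == 0 or any(c <= 0 for c in circ):
            raise InvalidConfigurationError("all row circumferences must be positive")
        object.__setattr__(self, "circumference_mm_by_row", circ)

    @property
    def n_rows(self) -> int:
        return len(self.circumference_mm_by_row)


@dataclass(frozen=True)
class ElectrodeGrid:
    """A rows-by-columns electrode layout in relative forearm coordinates.

    ``x_per_col`` holds the % circumference of each column; ``y_per_row``
    the % length of each row.  Both are shared by every channel in the
    corresponding column/row (columns are placed at equal *relative*
    spacing per row even when absolute mm spacing differs between rows).
    """

    n_rows: int
    n_cols: int
    x_per_col: tuple[float, ...]
    y_per_row: tuple[float, ...]
    span: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidConfigurationError("grid dimensions must be positive")
        if len(self.x_per_col) != self.n_cols or len(self.y_per_row) != self.n_rows:
            raise InvalidConfigurationError("coordinate arrays do not match grid shape")
        object.__setattr__(self, "x_per_col", tuple(float(x) for x in self.x_per_col))
        object.__setattr__(self, "y_per_row", tuple(float(y) for y in self.y_per_row))

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def channel_index(self, row: int, col: int) -> int:
        """Row-major channel index for 0-based ``(row, col)``."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"(row, col) = ({row}, {col}) outside {self.shape} grid")
        return row * self.n_cols + col

    def channel_position(self, channel: int) -> tuple[int, int]:
        """Inverse of :meth:`channel_index`."""
        if not (0 <= channel < self.n_channels):
            raise IndexError(f"channel {channel} outside [0, {self.n_channels})")
        return divmod(channel, self.n_cols)

    def channel_name(self, channel: int) -> str:
        row, col = self.channel_position(channel)
        return f"R{row + 1}C{col + 1}"

    @property
    def channel_names(self) -> list[str]:
        return [self.channel_name(ch) for ch in range(self.n_channels)]

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-channel ``(x, y)`` coordinate vectors, channel order."""
        x = np.tile(np.asarray(self.x_per_col), self.n_rows)
        y = np.repeat(np.asarray(self.y_per_row), self.n_cols)
        return x, y

    def coordinate_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """``(X, Y)`` coordinate matrices of shape ``(n_rows, n_cols)``."""
        x, y = self.coordinate_arrays()
        return x.reshape(self.shape), y.reshape(self.shape)

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "col_span_percent": list(self.span),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ElectrodeGrid":
        span = d.get("col_span_percent", [0.0, 100.0])
        return build_grid(int(d["n_rows"]), int(d["n_cols"]), (span[0], span[1]))


def build_grid(
    n_rows: int = 7,
    n_cols: int = 9,
    col_span_percent: tuple[float, float] = (0.0, 100.0),
) -> ElectrodeGrid:
    """Construct a regular electrode grid in relative coordinates.

    Rows are placed at the centers of ``n_rows`` equal segments of the
    forearm length: ``y_r = 100 * (r - 0.5) / n_rows`` (row 1 proximal).
    Columns are equally spaced over ``col_span_percent`` of the
    circumference.  When the span covers the full circumference the seam
    (0% == 100%) makes the axis periodic, so the ``n_cols`` electrodes
    are spaced ``span / n_cols`` apart with the endpoint excluded (wrap
    convention); for a partial span the endpoints are included and the
    spacing is ``span / (n_cols - 1)``.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions.  The default 7 x 9 gives the 63-channel layout.
    col_span_percent
        ``(start, stop)`` of the column span in % circumference.

    Returns
    -------
    ElectrodeGrid
    """
    if n_rows < 1 or n_cols < 1:
        raise InvalidConfigurationError("grid dimensions must be >= 1")
    lo, hi = float(col_span_percent[0]), float(col_span_percent[1])
    if not (0.0 <= lo < hi <= 100.0):
        raise InvalidConfigurationError(
            f"col_span_percent must satisfy 0 <= start < stop <= 100, got ({lo}, {hi})"
        )
    width = hi - lo
    if width >= _FULL_SPAN:  # full circumference: wrap, exclude the seam duplicate
        xs = lo + width * np.arange(n_cols) / n_cols
    elif n_cols == 1:
        xs = np.array([(lo + hi) / 2.0])
    else:
        xs = np.linspace(lo, hi, n_cols)
    ys = 100.0 * (np.arange(1, n_rows + 1) - 0.5) / n_rows
    return ElectrodeGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        x_per_col=tuple(xs),
        y_per_row=tuple(ys),
        span=(lo, hi),
    )


def channel_coordinates(grid: ElectrodeGrid, channel: int) -> tuple[float, float]:
    """``(x, y)`` relative coordinates of one channel.

    These are the per-channel coordinates the activation-map centroid is
    weighted over.

    Raises
    ------
    IndexError
        If ``channel`` is outside the grid.
    """
    row, col = grid.channel_position(channel)
    return grid.x_per_col[col], grid.y_per_row[row]
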