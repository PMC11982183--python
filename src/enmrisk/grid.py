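"""Grid and raster-stack containers shared by every pipeline stage.

All rasters in a run live on a single rectilinear grid of square cells
(:class:`GridSpec`). Coordinates are planar map units; ``(origin_x,
origin_y)`` is the lower-left corner of the grid and row 0 is the
northernmost (top) row, matching the ESRI ASCII grid convention used for
on-disk storage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["GridSpec", "EnvStack", "BinaryMap", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Raised when a grid, stack or generator specification is invalid."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster grid with square cells.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid shape; both must be >= 2.
    origin_x, origin_y : float
        Map coordinates of the lower-left corner.
    cell_size : float
        Cell edge length in map units (> 0).
    crs_tag : str
        Free-text identifier of the coordinate reference system.
    nodata : float
        Sentinel written to files for missing cells.
    """

    n_rows: int
    n_cols: int
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1.0
    crs_tag: str = "local-planar"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ConfigurationError(
                f"grid must be at least 2x2, got {self.n_rows}x{self.n_cols}"
            )
        if not self.cell_size > 0:
            raise ConfigurationError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer grid boundary."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinates as 2-D arrays of grid shape."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y + (self.n_rows - rows - 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) indices; -1 marks out-of-extent points."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row_from_bottom = np.floor((y - self.origin_y) / self.cell_size).astype(int)
        row = self.n_rows - 1 - row_from_bottom
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def row_y(self) -> np.ndarray:
        """y coordinate of each row's cell centers, top row first."""
        rows = np.arange(self.n_rows)
        return self.origin_y + (self.n_rows - rows - 0.5) * self.cell_size


def _check_same_grid(a: GridSpec, b: GridSpec, what: str = "rasters") -> None:
    if a != b:
        raise ConfigurationError(f"{what} are on different grids: {a} vs {b}")


@dataclass
class EnvStack:
    """A set of co-registered predictor rasters on one grid.

    ``data`` has shape ``(n_vars, n_rows, n_cols)``; ``mask`` is True on
    valid cells (shared across variables).
    """

    grid: GridSpec
    names: list[str]
    data: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.names):
            raise ConfigurationError(
                f"data shape {self.data.shape} does not match {len(self.names)} names"
            )
        if self.data.shape[1:] != self.grid.shape:
            raise ConfigurationError(
                f"data shape {self.data.shape[1:]} does not match grid {self.grid.shape}"
            )
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise ConfigurationError("mask shape does not match grid")

    @property
    def n_vars(self) -> int:
        return len(self.names)

    def layer(self, name: str) -> np.ndarray:
        try:
            i = self.names.index(name)
        except ValueError:
            raise KeyError(f"no layer named {name!r}; have {self.names}") from None
        return self.data[i]

    def table(self) -> np.ndarray:
        """Valid-cell values as an (n_valid_cells, n_vars) array."""
        return self.data[:, self.mask].T

    def extract(self, x, y) -> np.ndarray:
        """Predictor values at point coordinates, shape (n_points, n_vars).

        Points outside the grid extent or on invalid cells yield NaN rows.
        """
        row, col = self.grid.cell_of(x, y)
        row, col = np.atleast_1d(row), np.atleast_1d(col)
        out = np.full((row.size, self.n_vars), np.nan)
        inside = row >= 0
        r, c = row[inside], col[inside]
        good = self.mask[r, c]
        sel = np.flatnonzero(inside)[good]
        out[sel] = self.data[:, r[good], c[good]].T
        return out

    def copy(self) -> "EnvStack":
        return EnvStack(self.grid, list(self.names), self.data.copy(), self.mask.copy())

    def with_data(self, data: np.ndarray) -> "EnvStack":
        return EnvStack(self.grid, list(self.names), data, self.mask.copy())


@dataclass
class BinaryMap:
    """Thresholded presence-absence raster.

    ``values`` is uint8 with 1 = present, 0 = absent; cells where ``mask``
    is False are nodata. ``provenance`` records (model id, scenario id,
    threshold value, E) or similar free-form metadata.
    """

    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(np.uint8)
        if self.values.shape != self.grid.shape:
            raise ConfigurationError("values shape does not match grid")
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        self.values = np.where(self.mask, self.values, 0).astype(np.uint8)

    @property
    def presence(self) -> np.ndarray:
        """Boolean presence array (False on nodata cells)."""
        return (self.values == 1) & self.mask

    @property
    def n_present(self) -> int:
        return int(self.presence.sum())

    def copy(self) -> "BinaryMap":
        return BinaryMap(self.grid, self.values.copy(), self.mask.copy(), dict(self.provenance))
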