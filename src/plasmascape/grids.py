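"""Regular lon/lat grids used for time-spent rasters and isoscape surfaces.

Cells are half-open: ``[west, east) x [south, north)``. Grid origins are
snapped down to multiples of the cell size in global coordinates, so two
grids with the same cell size share cell-centre coordinates wherever they
overlap — this is what lets species surfaces be differenced cell-by-cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, UnsupportedExtentError


@dataclass(frozen=True)
class GridSpec:
    """A regular geographic grid.

    Parameters
    ----------
    cell_size : float
        Cell edge in degrees (same in lon and lat).
    west, south : float
        Lower-left corner (edge, not centre), degrees.
    n_lon, n_lat : int
        Number of columns / rows.
    """

    cell_size: float
    west: float
    south: float
    n_lon: int
    n_lat: int

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ConfigError("cell_size must be > 0")
        if self.n_lon < 1 or self.n_lat < 1:
            raise ConfigError("grid must have at least one cell per axis")
        if self.east > 180.0 + 1e-9 and self.west < 180.0:
            raise UnsupportedExtentError("grid spans the antimeridian")

    @property
    def east(self) -> float:
        return self.west + self.n_lon * self.cell_size

    @property
    def north(self) -> float:
        return self.south + self.n_lat * self.cell_size

    @classmethod
    def from_extent(cls, west, east, south, north, cell_size, snap=True):
        """Build the smallest snapped grid covering the extent."""
        if east <= west or north <= south:
            raise ConfigError("degenerate grid extent")
        if snap:
            west = np.floor(west / cell_size) * cell_size
            south = np.floor(south / cell_size) * cell_size
        n_lon = int(np.ceil((east - west) / cell_size - 1e-9))
        n_lat = int(np.ceil((north - south) / cell_size - 1e-9))
        return cls(cell_size, float(west), float(south), max(n_lon, 1), max(n_lat, 1))

    def lon_centers(self) -> np.ndarray:
        return self.west + (np.arange(self.n_lon) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        return self.south + (np.arange(self.n_lat) + 0.5) * self.cell_size

    def cell_of(self, lon, lat):
        """(col, row) indices of containing cells; half-open convention."""
        ix = np.floor((np.asarray(lon, float) - self.west) / self.cell_size).astype(int)
        iy = np.floor((np.asarray(lat, float) - self.south) / self.cell_size).astype(int)
        return ix, iy

    def contains(self, lon, lat):
        ix, iy = self.cell_of(lon, lat)
        return (ix >= 0) & (ix < self.n_lon) & (iy >= 0) & (iy < self.n_lat)

    def center_of(self, ix, iy):
        lon = self.west + (np.asarray(ix, float) + 0.5) * self.cell_size
        lat = self.south + (np.asarray(iy, float) + 0.5) * self.cell_size
        return lon, lat

    def meshgrid_centers(self):
        """(lon2d, lat2d) arrays of shape (n_lat, n_lon)."""
        return np.meshgrid(self.lon_centers(), self.lat_centers())
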