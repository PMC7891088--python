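"""Regular latitude/longitude grids with cell-center registration.

All rasters in the package live on a :class:`LatLonGrid`. Row 0 is the
northernmost row (map orientation); columns run west to east.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: km per degree of latitude on the authalic sphere (2*pi*R / 360).
KM_PER_DEGREE = 111.19508023353292


@dataclass(frozen=True)
class LatLonGrid:
    """Extent and resolution of a regular geographic grid.

    Parameters
    ----------
    lon_min, lon_max, lat_min, lat_max : float
        Outer edges of the grid in decimal degrees.
    resolution : float
        Cell size in decimal degrees. Both extents must be integer
        multiples of the resolution.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    resolution: float

    def __post_init__(self) -> None:
        for name in ("lon_min", "lon_max", "lat_min", "lat_max", "resolution"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        if not (self.lon_max > self.lon_min and self.lat_max > self.lat_min):
            raise ValueError("grid extent is empty or inverted")
        for name, span in (
            ("longitude", self.lon_max - self.lon_min),
            ("latitude", self.lat_max - self.lat_min),
        ):
            n = span / self.resolution
            if abs(n - round(n)) > 1e-8:
                raise ValueError(
                    f"{name} span {span} is not an integer multiple of "
                    f"resolution {self.resolution}"
                )

    @property
    def n_lon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.resolution))

    @property
    def n_lat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.resolution))

    @property
    def shape(self) -> tuple[int, int]:
        """(n_lat, n_lon) — raster shape, row 0 at the northern edge."""
        return (self.n_lat, self.n_lon)

    def lon_centers(self) -> np.ndarray:
        """Cell-center longitudes, west to east."""
        return self.lon_min + (np.arange(self.n_lon) + 0.5) * self.resolution

    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes, north to south (matching row order)."""
        return self.lat_max - (np.arange(self.n_lat) + 0.5) * self.resolution

    def lat_grid(self) -> np.ndarray:
        """2-D array of cell-center latitudes, shape ``self.shape``."""
        return np.broadcast_to(
            self.lat_centers()[:, None], self.shape
        ).copy()

    def lon_grid(self) -> np.ndarray:
        return np.broadcast_to(self.lon_centers()[None, :], self.shape).copy()

    def contains(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon)
        lat = np.asarray(lat)
        return (
            (lon >= self.lon_min)
            & (lon <= self.lon_max)
            & (lat >= self.lat_min)
            & (lat <= self.lat_max)
        )

    def cell_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) indices.

        Points on the outer east/north edges are assigned to the last
        cell so that the closed extent is fully covered.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.resolution).astype(int)
        row = np.floor((self.lat_max - lat) / self.resolution).astype(int)
        col = np.clip(col, 0, self.n_lon - 1)
        row = np.clip(row, 0, self.n_lat - 1)
        return row, col

    def __eq__(self, other) -> bool:
        if not isinstance(other, LatLonGrid):
            return NotImplemented
        return (
            abs(self.lon_min - other.lon_min) < 1e-9
            and abs(self.lon_max - other.lon_max) < 1e-9
            and abs(self.lat_min - other.lat_min) < 1e-9
            and abs(self.lat_max - other.lat_max) < 1e-9
            and abs(self.resolution - other.resolution) < 1e-12
        )

    def __hash__(self) -> int:
        return hash(
            (
                round(self.lon_min, 9),
                round(self.lon_max, 9),
                round(self.lat_min, 9),
                round(self.lat_max, 9),
                round(self.resolution, 12),
            )
        )

    def to_dict(self) -> dict:
        return {
            "lon_min": self.lon_min,
            "lon_max": self.lon_max,
            "lat_min": self.lat_min,
            "lat_max": self.lat_max,
            "resolution": self.resolution,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LatLonGrid":
        return cls(
            lon_min=float(d["lon_min"]),
            lon_max=float(d["lon_max"]),
            lat_min=float(d["lat_min"]),
            lat_max=float(d["lat_max"]),
            resolution=float(d["resolution"]),
        )


#: Default desk-scale modelling window (a coarse sub-window of the
#: Afro-Asian extent used for full runs).
DEFAULT_GRID = LatLonGrid(
    lon_min=-40.0, lon_max=60.0, lat_min=-40.0, lat_max=40.0, resolution=0.5
)
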