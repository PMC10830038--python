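"""Equal-area grid, projection, and raster containers.

All distance and area computations in the package happen in a projected
equal-area plane (metres).  Geographic coordinates (WGS84 lon/lat) are kept
only for solar geometry and the migrant latitude rule.  The projection is a
spherical Lambert azimuthal equal-area (LAEA) centred on the study area,
implemented from the standard closed-form equations on the authalic sphere.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

# authalic Earth radius (m)
EARTH_RADIUS = 6_371_007.2


@dataclass(frozen=True)
class LambertAzimuthalEqualArea:
    """Spherical LAEA projection centred at (lat0, lon0), in degrees."""

    lat0: float = 43.0
    lon0: float = -107.5
    radius: float = EARTH_RADIUS

    def forward(self, lon, lat):
        """Project lon/lat (deg) to x/y (m). Accepts scalars or arrays."""
        lam = np.radians(np.asarray(lon, dtype=float) - self.lon0)
        phi = np.radians(np.asarray(lat, dtype=float))
        phi0 = math.radians(self.lat0)
        denom = 1.0 + math.sin(phi0) * np.sin(phi) + math.cos(phi0) * np.cos(phi) * np.cos(lam)
        with np.errstate(divide="ignore", invalid="ignore"):
            k = np.sqrt(2.0 / denom)
        x = self.radius * k * np.cos(phi) * np.sin(lam)
        y = self.radius * k * (math.cos(phi0) * np.sin(phi) - math.sin(phi0) * np.cos(phi) * np.cos(lam))
        return x, y

    def inverse(self, x, y):
        """Inverse projection: x/y (m) to lon/lat (deg)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        phi0 = math.radians(self.lat0)
        rho = np.hypot(x, y)
        c = 2.0 * np.arcsin(np.clip(rho / (2.0 * self.radius), -1.0, 1.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.where(
                rho == 0.0,
                phi0,
                np.arcsin(np.clip(np.cos(c) * math.sin(phi0) + y * np.sin(c) * math.cos(phi0) / np.where(rho == 0, 1, rho), -1, 1)),
            )
            lam = np.arctan2(
                x * np.sin(c),
                rho * math.cos(phi0) * np.cos(c) - y * math.sin(phi0) * np.sin(c),
            )
        lon = self.lon0 + np.degrees(np.where(rho == 0.0, 0.0, lam))
        lat = np.degrees(phi)
        return lon, lat

    def to_dict(self) -> dict:
        return {"proj": "laea", "lat0": self.lat0, "lon0": self.lon0, "radius": self.radius}

    @classmethod
    def from_dict(cls, d: dict) -> "LambertAzimuthalEqualArea":
        return cls(lat0=d["lat0"], lon0=d["lon0"], radius=d.get("radius", EARTH_RADIUS))


@dataclass(frozen=True)
class Grid:
    """North-up cell-centred raster grid in the projected plane.

    Row 0 is the northernmost row.  ``(x0, y0)`` is the outer corner of the
    lower-left cell; cell centres are offset by half a cell.
    """

    nrows: int
    ncols: int
    resolution: float  # m
    x0: float = 0.0
    y0: float = 0.0
    crs: LambertAzimuthalEqualArea = field(default_factory=LambertAzimuthalEqualArea)

    def __post_init__(self):
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.resolution <= 0:
            raise ValueError("grid resolution must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def cell_area_km2(self) -> float:
        return (self.resolution / 1000.0) ** 2

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer grid boundary."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.ncols * self.resolution,
            self.y0 + self.nrows * self.resolution,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (nrows, ncols) of x and y cell-centre coordinates."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.resolution
        ys = self.y0 + (self.nrows - np.arange(self.nrows) - 0.5) * self.resolution
        return np.meshgrid(xs, ys)

    def xy_to_rowcol(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map projected coordinates to integer (row, col); may be out of range."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.resolution).astype(int)
        row = np.floor((self.y0 + self.nrows * self.resolution - y) / self.resolution).astype(int)
        return row, col

    def contains_xy(self, x, y) -> np.ndarray:
        row, col = self.xy_to_rowcol(x, y)
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)

    def sample(self, values: np.ndarray, x, y, fill=np.nan) -> np.ndarray:
        """Sample a (nrows, ncols) array at projected points (nearest cell)."""
        row, col = self.xy_to_rowcol(x, y)
        ok = (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)
        out = np.full(np.shape(row), fill, dtype=float)
        out[ok] = values[row[ok], col[ok]]
        return out

    def to_dict(self) -> dict:
        return {
            "nrows": self.nrows,
            "ncols": self.ncols,
            "resolution": self.resolution,
            "x0": self.x0,
            "y0": self.y0,
            "crs": self.crs.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Grid":
        return cls(
            nrows=d["nrows"],
            ncols=d["ncols"],
            resolution=d["resolution"],
            x0=d["x0"],
            y0=d["y0"],
            crs=LambertAzimuthalEqualArea.from_dict(d["crs"]),
        )


class AlignmentError(ValueError):
    """Raised when rasters with different grids are combined."""


def assert_aligned(a: Grid, b: Grid) -> None:
    if a.shape != b.shape or a.resolution != b.resolution or (a.x0, a.y0) != (b.x0, b.y0):
        raise AlignmentError(f"grids are not aligned: {a.to_dict()} vs {b.to_dict()}")


@dataclass
class Raster:
    """A single 2-D layer on a Grid. NaN encodes NoData."""

    grid: Grid
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.shape:
            raise ValueError(f"data shape {self.data.shape} != grid shape {self.grid.shape}")

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.data)

    def copy(self) -> "Raster":
        return Raster(self.grid, self.data.copy())

    def sample(self, x, y, fill=np.nan) -> np.ndarray:
        return self.grid.sample(self.data, x, y, fill=fill)


@dataclass
class LayerMeta:
    """Provenance of a covariate layer: base variable, category, focal window."""

    name: str
    base: str
    category: str
    extent_m: float | None = None  # focal window radius descriptor (m)
    statistic: str | None = None  # mean | sd | min | max
    categorical: bool = False

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "base": self.base,
            "category": self.category,
            "extent_m": self.extent_m,
            "statistic": self.statistic,
            "categorical": self.categorical,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LayerMeta":
        return cls(**d)


class RasterStack:
    """An ordered set of aligned layers with per-layer metadata."""

    def __init__(self, grid: Grid):
        self.grid = grid
        self._layers: dict[str, np.ndarray] = {}
        self._meta: dict[str, LayerMeta] = {}

    def add(self, data: np.ndarray, meta: LayerMeta) -> None:
        data = np.asarray(data, dtype=float)
        if data.shape != self.grid.shape:
            raise AlignmentError(f"layer {meta.name!r} shape {data.shape} != grid {self.grid.shape}")
        if meta.name in self._layers:
            raise ValueError(f"duplicate layer name {meta.name!r}")
        self._layers[meta.name] = data
        self._meta[meta.name] = meta

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __getitem__(self, name: str) -> np.ndarray:
        return self._layers[name]

    def meta(self, name: str) -> LayerMeta:
        return self._meta[name]

    def subset(self, names) -> "RasterStack":
        out = RasterStack(self.grid)
        for n in names:
            out.add(self._layers[n].copy(), self._meta[n])
        return out

    def sample(self, names, x, y) -> np.ndarray:
        """(n_points, n_layers) matrix of layer values at projected points."""
        cols = [self.grid.sample(self._layers[n], x, y) for n in names]
        return np.column_stack(cols) if cols else np.empty((np.size(x), 0))

    def metadata_json(self) -> str:
        return json.dumps(
            {"grid": self.grid.to_dict(), "layers": [self._meta[n].to_dict() for n in self.names]},
            indent=2,
        )
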