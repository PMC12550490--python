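"""Gridded climate layers and plain-text (ESRI ASCII grid) raster I/O.

Layers live on a common lon/lat grid with a fixed angular cell size and a
nominal planar cell size in km used for area arithmetic (toy scale — no
geodesic correction, so suitable-area sums stay exact in tests).
Missing cells are NaN.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

NODATA = -9999.0


@dataclass
class RasterStack:
    """Named co-registered layers on one grid."""

    layers: dict[str, np.ndarray]
    cell_size_deg: float = 0.05
    cell_size_km: float = 4.5
    lon0: float = 0.0  # west edge
    lat0: float = 0.0  # north edge
    period: str = "present"

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.layers.values()}
        if len(shapes) > 1:
            raise ValueError("layers do not share a grid")
        self.layers = {k: np.asarray(v, dtype=float) for k, v in self.layers.items()}

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def cell_area_km2(self) -> float:
        return self.cell_size_km**2

    def lonlat_of(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinates for row/col indices."""
        lon = self.lon0 + (np.asarray(cols) + 0.5) * self.cell_size_deg
        lat = self.lat0 - (np.asarray(rows) + 0.5) * self.cell_size_deg
        return lon, lat

    def index_of(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of coordinates (clipped to the grid)."""
        nrow, ncol = self.shape
        col = np.clip(((np.asarray(lon) - self.lon0) / self.cell_size_deg).astype(int), 0, ncol - 1)
        row = np.clip(((self.lat0 - np.asarray(lat)) / self.cell_size_deg).astype(int), 0, nrow - 1)
        return row, col

    def valid_mask(self) -> np.ndarray:
        """Cells with all layers non-missing."""
        m = np.ones(self.shape, dtype=bool)
        for arr in self.layers.values():
            m &= np.isfinite(arr)
        return m

    def table(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Cells-by-layers value matrix over ``mask`` (default: valid cells)."""
        if mask is None:
            mask = self.valid_mask()
        return np.column_stack([self.layers[name][mask] for name in self.layer_names])

    def crop(self, row0: int, row1: int, col0: int, col1: int) -> "RasterStack":
        return RasterStack(
            layers={k: v[row0:row1, col0:col1].copy() for k, v in self.layers.items()},
            cell_size_deg=self.cell_size_deg,
            cell_size_km=self.cell_size_km,
            lon0=self.lon0 + col0 * self.cell_size_deg,
            lat0=self.lat0 - row0 * self.cell_size_deg,
            period=self.period,
        )


def write_ascii_grid(arr: np.ndarray, path, lon0: float, lat0: float, cell_size_deg: float) -> None:
    nrow, ncol = arr.shape
    out = np.where(np.isfinite(arr), arr, NODATA)
    header = (
        f"ncols {ncol}\nnrows {nrow}\n"
        f"xllcorner {lon0}\nyllcorner {lat0 - nrow * cell_size_deg}\n"
        f"cellsize {cell_size_deg}\nNODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.6g")


def read_ascii_grid(path) -> tuple[np.ndarray, float, float, float]:
    """Return (array, lon0, lat0_north, cell_size_deg)."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        arr = np.loadtxt(fh)
    arr = np.atleast_2d(arr)
    nodata = meta.get("nodata_value", NODATA)
    arr[arr == nodata] = np.nan
    lat0 = meta["yllcorner"] + meta["nrows"] * meta["cellsize"]
    return arr, meta["xllcorner"], lat0, meta["cellsize"]


def write_stack(stack: RasterStack, directory, prefix: str | None = None) -> list[str]:
    os.makedirs(directory, exist_ok=True)
    prefix = prefix or stack.period
    paths = []
    for name, arr in stack.layers.items():
        p = os.path.join(directory, f"{prefix}_{name}.asc")
        write_ascii_grid(arr, p, stack.lon0, stack.lat0, stack.cell_size_deg)
        paths.append(p)
    return paths


def read_stack(paths: dict[str, str], cell_size_km: float = 4.5, period: str = "present") -> RasterStack:
    layers = {}
    geo = None
    for name, p in paths.items():
        arr, lon0, lat0, cs = read_ascii_grid(p)
        if geo is None:
            geo = (lon0, lat0, cs)
        elif geo != (lon0, lat0, cs):
            raise ValueError(f"layer {name} not co-registered")
        layers[name] = arr
    assert geo is not None
    return RasterStack(layers, cell_size_deg=geo[2], cell_size_km=cell_size_km, lon0=geo[0], lat0=geo[1], period=period)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km (broadcasting over array inputs)."""
    r = 6371.0088
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * r * np.arcsin(np.sqrt(a))
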