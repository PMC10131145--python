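"""Lightweight projected-raster and GeoJSON helpers.

All geometry in this package lives in a single projected (metric) Cartesian
frame.  Rasters are held as a :class:`Grid` — a north-up 2-D array with a
lower-left anchor and square cells — and serialized as ESRI ASCII grids,
a plain-text interchange format readable by every GIS.  Vector layers are
shapely geometries serialized as GeoJSON FeatureCollections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import mapping, shape


class CoverageError(ValueError):
    """A buffer or query point falls outside the raster extent."""


class ProjectionError(ValueError):
    """Coordinates look geographic (degrees) where metres are required."""


def check_projected(xs, ys) -> None:
    """Reject coordinates that look like lon/lat degrees.

    Buffer statistics are only meaningful in a projected frame; a bounding
    box inside [-180, 180] x [-90, 90] is taken as geographic.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0:
        return
    if (np.abs(xs).max() <= 180.0) and (np.abs(ys).max() <= 90.0):
        raise ProjectionError(
            "coordinates fall inside [-180, 180] x [-90, 90]; "
            "projected metric coordinates are required"
        )


@dataclass
class Grid:
    """North-up raster with square cells on a projected frame.

    ``values[0, :]`` is the northernmost row; ``(x0, y0)`` is the lower-left
    corner of the lower-left cell; ``cellsize`` is in metres.
    """

    values: np.ndarray
    x0: float
    y0: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the covered rectangle."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.nx * self.cellsize,
            self.y0 + self.ny * self.cellsize,
        )

    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.nx) + 0.5) * self.cellsize

    def y_centers(self) -> np.ndarray:
        """Cell-centre y per row, row 0 = northernmost."""
        top = self.y0 + self.ny * self.cellsize
        return top - (np.arange(self.ny) + 0.5) * self.cellsize

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        xmin, ymin, xmax, ymax = self.extent
        if not (xmin <= x <= xmax and ymin <= y <= ymax):
            raise CoverageError(f"point ({x:g}, {y:g}) outside raster extent")
        col = min(int((x - self.x0) / self.cellsize), self.nx - 1)
        row = min(int((self.y0 + self.ny * self.cellsize - y) / self.cellsize), self.ny - 1)
        return row, col

    def value_at(self, x: float, y: float) -> float:
        row, col = self.index_of(x, y)
        return float(self.values[row, col])

    def cells_in_disk(self, x: float, y: float, radius: float) -> np.ndarray:
        """Values of cells whose centres lie in the closed disk.

        Raises :class:`CoverageError` when the disk does not even touch the
        raster extent (distinguishing "off the map" from "small radius").
        """
        if radius <= 0:
            raise ValueError("radius must be positive")
        xmin, ymin, xmax, ymax = self.extent
        if x + radius < xmin or x - radius > xmax or y + radius < ymin or y - radius > ymax:
            raise CoverageError("buffer entirely outside raster extent")
        xc = self.x_centers()
        yc = self.y_centers()
        jmask = np.abs(xc - x) <= radius
        imask = np.abs(yc - y) <= radius
        if not jmask.any() or not imask.any():
            return np.empty(0)
        sub = self.values[np.ix_(imask, jmask)]
        dx = xc[jmask] - x
        dy = yc[imask] - y
        inside = (dy[:, None] ** 2 + dx[None, :] ** 2) <= radius**2
        return sub[inside]

    def write_ascii(self, path) -> None:
        header = (
            f"ncols {self.nx}\n"
            f"nrows {self.ny}\n"
            f"xllcorner {self.x0:.6f}\n"
            f"yllcorner {self.y0:.6f}\n"
            f"cellsize {self.cellsize:.6f}\n"
            f"NODATA_value {self.nodata:g}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.values, fmt="%.6g")

    @classmethod
    def read_ascii(cls, path) -> "Grid":
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            values = np.loadtxt(fh)
        values = np.atleast_2d(values)
        return cls(
            values=values,
            x0=meta["xllcorner"],
            y0=meta["yllcorner"],
            cellsize=meta["cellsize"],
            nodata=meta.get("nodata_value", -9999.0),
        )


def write_geojson(path, geometries, properties=None) -> None:
    """Write shapely geometries (+ parallel property dicts) as a FeatureCollection."""
    properties = properties if properties is not None else [{} for _ in geometries]
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geometries, properties, strict=True)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path):
    """Return (geometries, properties) lists from a GeoJSON FeatureCollection."""
    with open(path) as fh:
        fc = json.load(fh)
    geoms = [shape(f["geometry"]) for f in fc["features"]]
    props = [f.get("properties") or {} for f in fc["features"]]
    return geoms, props
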