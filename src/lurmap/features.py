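"""Spatial buffer predictors, weekly temporal predictors, design assembly
and standardization.

Spatial predictors are circular-buffer statistics (radii 50/100/200/500 m by
default) around each location: clipped road/river length, land-use class
area and raster means by cell-centre containment, amenity counts/presence,
area-weighted population density, point-to-nearest distances (inverse
distance clamped at 1 m), and the site-cell elevation.  The closed-disk
convention applies throughout: geometry exactly on the buffer boundary is
inside.  Temporal predictors are the weekly meteorology values, rainfall
presence, and month-of-year indicators against a reference month.

Each predictor carries an a-priori expected coefficient sign used by the
selection stage's sign screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import Point

from .geo import Grid, check_projected, CoverageError
from .synthetic_city import (
    CityScene,
    SamplingDesign,
    LANDUSE_CODE,
)

DEFAULT_BUFFERS = (50.0, 100.0, 200.0, 500.0)
_QUAD_SEGS = 96  # disk polygon resolution; radial error < 2e-4 * r


class DegeneratePredictorError(ValueError):
    """A column with zero variance cannot be standardized."""


# ---------------------------------------------------------------------------
# Buffer statistics (closed-disk convention)
# ---------------------------------------------------------------------------


def _disk(center, radius: float):
    if radius <= 0:
        raise ValueError("radius must be positive")
    return Point(center).buffer(radius, quad_segs=_QUAD_SEGS)


def line_length_in_buffer(lines, center, radius: float) -> float:
    """Total clipped length (m) of polylines intersecting the closed disk."""
    lines = list(lines)
    if lines:
        xs = [c[0] for g in lines for c in g.coords] + [center[0]]
        ys = [c[1] for g in lines for c in g.coords] + [center[1]]
        check_projected(xs, ys)
    disk = _disk(center, radius)
    return float(sum(g.intersection(disk).length for g in lines))


def raster_class_area_in_buffer(raster: Grid, cls: int, center, radius: float) -> float:
    """Area (m²) of raster cells of a class whose centres lie in the closed disk."""
    vals = raster.cells_in_disk(center[0], center[1], radius)
    return float((vals == cls).sum()) * raster.cellsize**2


def raster_mean_in_buffer(raster: Grid, center, radius: float) -> float:
    """Arithmetic mean of cell-centre values in the closed disk; error if none."""
    vals = raster.cells_in_disk(center[0], center[1], radius)
    if vals.size == 0:
        raise CoverageError("no raster cell centre falls inside the buffer")
    return float(vals.mean())


def point_count_in_buffer(points, center, radius: float) -> int:
    """Number of points at distance <= radius (closed disk)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not points:
        return 0
    xy = np.array([(p.x, p.y) if isinstance(p, Point) else tuple(p) for p in points])
    d = np.hypot(xy[:, 0] - center[0], xy[:, 1] - center[1])
    return int((d <= radius).sum())


def distance_to_nearest(features, site, mode: str = "euclidean") -> float:
    """Minimum point-to-geometry distance (m); ``inverse`` = 1/max(d, 1 m)."""
    features = list(features)
    if not features:
        raise ValueError("empty feature set: distance undefined")
    p = Point(site)
    d = min(g.distance(p) for g in features)
    if mode == "euclidean":
        return float(d)
    if mode == "inverse":
        return float(1.0 / max(d, 1.0))
    raise ValueError("mode must be 'euclidean' or 'inverse'")


def population_density_in_buffer(zones, center, radius: float) -> float:
    """Area-weighted mean density (people/km²) over the disk; gaps count as 0."""
    disk = _disk(center, radius)
    total = 0.0
    for poly, dens in zones:
        if dens < 0:
            raise ValueError("negative population density")
        inter = poly.intersection(disk)
        if not inter.is_empty:
            total += dens * inter.area
    return total / disk.area


# ---------------------------------------------------------------------------
# Predictor registry
# ---------------------------------------------------------------------------

_STATS = (
    "line_length",
    "class_area",
    "raster_mean",
    "point_count",
    "presence",
    "avg_density",
    "distance",
    "inverse_distance",
    "site_value",
    "weekly_value",
    "rain_presence",
    "month_dummies",
)


@dataclass(frozen=True)
class Predictor:
    """One candidate predictor: a layer, a statistic, optional buffers, and
    the a-priori expected sign of its association with concentration."""

    name: str
    layer: str
    stat: str
    buffers: tuple[float, ...] = ()
    expected_sign: str = "unconstrained"  # "+", "-", "unconstrained"
    kind: str = "spatial"
    cls: str | None = None
    continuous: bool = True

    def __post_init__(self) -> None:
        if self.stat not in _STATS:
            raise ValueError(f"unknown stat {self.stat!r}")
        if self.expected_sign not in ("+", "-", "unconstrained"):
            raise ValueError("expected_sign must be '+', '-' or 'unconstrained'")
        buffered = self.stat in ("line_length", "class_area", "raster_mean",
                                 "point_count", "presence", "avg_density")
        if self.kind == "spatial" and buffered and not self.buffers:
            raise ValueError(f"buffered predictor {self.name!r} needs >=1 buffer radius")
        if self.stat in ("distance", "inverse_distance", "site_value") and self.buffers:
            raise ValueError(f"{self.stat} predictor {self.name!r} takes no buffers")


@dataclass
class PredictorRegistry:
    entries: list[Predictor]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("predictor names must be unique")

    def spatial(self) -> list[Predictor]:
        return [e for e in self.entries if e.kind == "spatial"]

    def temporal(self) -> list[Predictor]:
        return [e for e in self.entries if e.kind == "temporal"]

    def get(self, name: str) -> Predictor:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def subset(self, names) -> "PredictorRegistry":
        names = set(names)
        return PredictorRegistry([e for e in self.entries if e.name in names])


def default_registry(
    buffers: tuple[float, ...] = DEFAULT_BUFFERS,
    include_wind_direction: bool = False,
) -> PredictorRegistry:
    """The standard candidate inventory for this kind of LUR.

    Wind direction is excluded by default (circular variable); setting
    ``include_wind_direction`` adds a sine/cosine pair.
    """
    e = [
        Predictor("major_road_length", "roads", "line_length", buffers, "+", cls="major"),
        Predictor("secondary_road_length", "roads", "line_length", buffers, "+", cls="secondary"),
        Predictor("minor_road_length", "roads", "line_length", buffers, "+", cls="minor"),
        Predictor("river_length", "rivers", "line_length", buffers, "-"),
        Predictor("cbi_area", "landuse", "class_area", buffers, "+", cls="CBI"),
        Predictor("informal_area", "landuse", "class_area", buffers, "+", cls="informal_residential"),
        Predictor("formal_area", "landuse", "class_area", buffers, "+", cls="formal_residential"),
        Predictor("open_area", "landuse", "class_area", buffers, "-", cls="other"),
        Predictor("ndvi", "ndvi", "raster_mean", buffers, "-"),
        Predictor("elevation", "elevation", "site_value", (), "-"),
        Predictor("population_density", "population_zones", "avg_density", buffers, "+"),
        Predictor("bus_stop_count", "amenities", "point_count", buffers, "+", cls="bus_stop"),
        Predictor("bus_terminal_count", "amenities", "point_count", buffers, "+", cls="bus_terminal"),
        Predictor("restaurant_count", "amenities", "point_count", buffers, "+", cls="restaurant"),
        Predictor("shopping_center_count", "amenities", "point_count", buffers, "+", cls="shopping_center"),
        Predictor("dist_major_road", "roads", "distance", (), "-", cls="major"),
        Predictor("inv_dist_major_road", "roads", "inverse_distance", (), "+", cls="major"),
        Predictor("dist_airport", "airport", "distance", (), "-"),
        # temporal
        Predictor("temperature", "met", "weekly_value", (), "unconstrained", kind="temporal"),
        Predictor("relative_humidity", "met", "weekly_value", (), "-", kind="temporal"),
        Predictor("wind_speed", "met", "weekly_value", (), "-", kind="temporal"),
        Predictor("rainfall_presence", "met", "rain_presence", (), "-", kind="temporal", continuous=False),
        Predictor("mixing_layer_depth", "met", "weekly_value", (), "-", kind="temporal"),
        Predictor("water_vapor_mixing_ratio", "met", "weekly_value", (), "unconstrained", kind="temporal"),
        Predictor("solar_radiation", "met", "weekly_value", (), "unconstrained", kind="temporal"),
        Predictor("month", "met", "month_dummies", (), "unconstrained", kind="temporal", continuous=False),
    ]
    if include_wind_direction:
        e.append(Predictor("wind_dir_sin", "met", "weekly_value", (), "unconstrained", kind="temporal"))
        e.append(Predictor("wind_dir_cos", "met", "weekly_value", (), "unconstrained", kind="temporal"))
    return PredictorRegistry(e)


# ---------------------------------------------------------------------------
# Column metadata and the design matrix container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColumnMeta:
    base: str
    buffer: float | None
    expected_sign: str
    continuous: bool
    kind: str


@dataclass
class PredictorMatrix:
    """Site-week design table plus per-column metadata and standardization.

    ``data`` holds ``site_id`` and ``week_index`` key columns followed by one
    column per realized predictor (e.g. ``major_road_length_500``).
    ``standardization`` maps column → (mean, sample sd) on the original
    scale, stored when :func:`standardize_columns` is applied and reused
    verbatim for any later prediction input.
    """

    data: pd.DataFrame
    spatial_columns: list[str]
    temporal_columns: list[str]
    column_meta: dict[str, ColumnMeta]
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def predictor_columns(self) -> list[str]:
        return self.spatial_columns + self.temporal_columns

    def copy(self) -> "PredictorMatrix":
        return PredictorMatrix(
            data=self.data.copy(),
            spatial_columns=list(self.spatial_columns),
            temporal_columns=list(self.temporal_columns),
            column_meta=dict(self.column_meta),
            standardization=dict(self.standardization),
        )


def _column_name(base: str, buffer: float | None) -> str:
    return base if buffer is None else f"{base}_{buffer:g}"


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


class _SceneIndex:
    """Cached spatial indexes over a scene's layers."""

    def __init__(self, scene: CityScene):
        self.scene = scene
        self._lines: dict[tuple[str, str | None], tuple[list, STRtree | None]] = {}
        self._points: dict[str, np.ndarray] = {}
        self._zone_tree: STRtree | None = None
        self._zone_list = scene.population_zones

    def lines(self, layer: str, cls: str | None):
        key = (layer, cls)
        if key not in self._lines:
            geoms = (
                self.scene.roads_of_class(cls) if layer == "roads" else list(self.scene.rivers)
            )
            tree = STRtree(geoms) if geoms else None
            self._lines[key] = (geoms, tree)
        return self._lines[key]

    def points(self, kind: str) -> np.ndarray:
        if kind not in self._points:
            pts = self.scene.amenity_points(kind)
            self._points[kind] = (
                np.array([(p.x, p.y) for p in pts]) if pts else np.empty((0, 2))
            )
        return self._points[kind]

    def zone_tree(self) -> STRtree | None:
        if self._zone_tree is None and self._zone_list:
            self._zone_tree = STRtree([g for g, _ in self._zone_list])
        return self._zone_tree

    def raster(self, layer: str) -> Grid:
        return {"landuse": self.scene.landuse, "ndvi": self.scene.ndvi,
                "elevation": self.scene.elevation}[layer]


def _extract_one(idx: _SceneIndex, entry: Predictor, x: float, y: float,
                 radius: float | None) -> float:
    scene = idx.scene
    if entry.stat == "line_length":
        geoms, tree = idx.lines(entry.layer, entry.cls)
        if not geoms:
            return 0.0
        disk = _disk((x, y), radius)
        cand = tree.query(disk)
        return float(sum(geoms[i].intersection(disk).length for i in cand))
    if entry.stat == "class_area":
        return raster_class_area_in_buffer(
            idx.raster(entry.layer), LANDUSE_CODE[entry.cls], (x, y), radius
        )
    if entry.stat == "raster_mean":
        return raster_mean_in_buffer(idx.raster(entry.layer), (x, y), radius)
    if entry.stat in ("point_count", "presence"):
        xy = idx.points(entry.cls)
        if xy.shape[0] == 0:
            return 0.0
        d = np.hypot(xy[:, 0] - x, xy[:, 1] - y)
        n = int((d <= radius).sum())
        return float(n > 0) if entry.stat == "presence" else float(n)
    if entry.stat == "avg_density":
        tree = idx.zone_tree()
        if tree is None:
            return 0.0
        disk = _disk((x, y), radius)
        total = 0.0
        for i in tree.query(disk):
            poly, dens = idx._zone_list[i]
            inter = poly.intersection(disk)
            if not inter.is_empty:
                total += dens * inter.area
        return total / disk.area
    if entry.stat == "distance" or entry.stat == "inverse_distance":
        if entry.layer == "airport":
            geoms = [scene.airport]
        else:
            geoms, _ = idx.lines(entry.layer, entry.cls)
        mode = "euclidean" if entry.stat == "distance" else "inverse"
        return distance_to_nearest(geoms, (x, y), mode=mode)
    if entry.stat == "site_value":
        return idx.raster(entry.layer).value_at(x, y)
    raise ValueError(f"stat {entry.stat!r} is not a spatial statistic")


def compute_spatial_features(
    scene: CityScene, sites: pd.DataFrame, registry: PredictorRegistry
) -> pd.DataFrame:
    """Per-site spatial predictor table (one column per variable × buffer).

    ``sites`` needs ``site_id``, ``x`` and ``y`` columns; every registry
    layer must exist on the scene.
    """
    check_projected(sites["x"], sites["y"])
    idx = _SceneIndex(scene)
    cols: dict[str, list[float]] = {}
    for entry in registry.spatial():
        radii = entry.buffers if entry.buffers else (None,)
        for r in radii:
            name = _column_name(entry.name, r)
            cols[name] = [
                _extract_one(idx, entry, x, y, r)
                for x, y in zip(sites["x"].to_numpy(), sites["y"].to_numpy())
            ]
    out = pd.DataFrame(cols)
    out.insert(0, "site_id", sites["site_id"].to_numpy())
    return out


def weekly_temporal_features(
    met: pd.DataFrame, registry: PredictorRegistry, reference_month: int = 3
) -> pd.DataFrame:
    """Per-week temporal predictor record (meteorology + month indicators).

    Month is encoded as 0/1 indicator columns for every month present in the
    meteorology table except the reference month.
    """
    required = {"week_index", "month"}
    if not required.issubset(met.columns):
        raise KeyError("met table needs week_index and month columns")
    out = pd.DataFrame({"week_index": met["week_index"].to_numpy()})
    for entry in registry.temporal():
        if entry.stat == "weekly_value":
            src = {
                "wind_dir_sin": lambda m: np.sin(np.deg2rad(m["wind_direction"])),
                "wind_dir_cos": lambda m: np.cos(np.deg2rad(m["wind_direction"])),
            }.get(entry.name)
            if src is not None:
                out[entry.name] = src(met).to_numpy()
            else:
                if entry.name not in met.columns:
                    raise KeyError(f"meteorology table lacks column {entry.name!r}")
                out[entry.name] = met[entry.name].to_numpy()
        elif entry.stat == "rain_presence":
            out[entry.name] = (met["rainfall_presence"].to_numpy() > 0).astype(float)
        elif entry.stat == "month_dummies":
            months = sorted(met["month"].unique())
            for m in months:
                if m == reference_month:
                    continue
                out[f"month_{m}"] = (met["month"].to_numpy() == m).astype(float)
    return out


def assemble_design(
    scene: CityScene,
    design: SamplingDesign,
    met: pd.DataFrame,
    registry: PredictorRegistry,
    reference_month: int = 3,
) -> PredictorMatrix:
    """Assemble the site-week design table from a scene, design and meteorology."""
    spatial = compute_spatial_features(scene, design.sites, registry)
    temporal = weekly_temporal_features(met, registry, reference_month)
    records = design.records()
    missing_weeks = set(records["week_index"]) - set(temporal["week_index"])
    if missing_weeks:
        raise ValueError(f"meteorology missing for weeks {sorted(missing_weeks)}")
    data = records.merge(spatial, on="site_id", how="left").merge(
        temporal, on="week_index", how="left"
    )
    spatial_cols = [c for c in spatial.columns if c != "site_id"]
    temporal_cols = [c for c in temporal.columns if c != "week_index"]

    meta: dict[str, ColumnMeta] = {}
    for entry in registry.spatial():
        radii = entry.buffers if entry.buffers else (None,)
        for r in radii:
            meta[_column_name(entry.name, r)] = ColumnMeta(
                entry.name, r, entry.expected_sign, entry.continuous, "spatial"
            )
    for entry in registry.temporal():
        if entry.stat == "month_dummies":
            for c in temporal_cols:
                if c.startswith("month_"):
                    meta[c] = ColumnMeta("month", None, entry.expected_sign, False, "temporal")
        elif entry.name in temporal_cols:
            meta[entry.name] = ColumnMeta(
                entry.name, None, entry.expected_sign, entry.continuous, "temporal"
            )
    if data[spatial_cols + temporal_cols].isna().any().any():
        raise ValueError("assembled design contains missing cells")
    return PredictorMatrix(
        data=data,
        spatial_columns=spatial_cols,
        temporal_columns=temporal_cols,
        column_meta=meta,
    )


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


def prune_degenerate(matrix: PredictorMatrix) -> tuple[PredictorMatrix, list[str]]:
    """Drop candidate columns with zero variance (e.g. an amenity count that
    is zero in every 50 m buffer); returns the pruned matrix and the names."""
    out = matrix.copy()
    dropped = []
    for c in matrix.predictor_columns:
        x = out.data[c].to_numpy(dtype=float)
        if np.all(x == x[0]):
            dropped.append(c)
            out.data = out.data.drop(columns=[c])
            out.column_meta.pop(c, None)
            if c in out.spatial_columns:
                out.spatial_columns.remove(c)
            else:
                out.temporal_columns.remove(c)
    return out, dropped


def standardize_columns(
    matrix: PredictorMatrix, columns: list[str] | None = None
) -> PredictorMatrix:
    """Centre and scale continuous columns; store (mean, sample sd) per column.

    Sample sd uses the n−1 denominator.  The stored parameters are reused
    verbatim for any later prediction input (see ``apply_standardization``).
    """
    if columns is None:
        columns = [
            c for c in matrix.predictor_columns if matrix.column_meta[c].continuous
        ]
    out = matrix.copy()
    for c in columns:
        x = out.data[c].to_numpy(dtype=float)
        mean = float(x.mean())
        sd = float(x.std(ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            raise DegeneratePredictorError(f"column {c!r} has zero variance")
        out.data[c] = (x - mean) / sd
        out.standardization[c] = (mean, sd)
    return out


def apply_standardization(
    df: pd.DataFrame, params: dict[str, tuple[float, float]]
) -> pd.DataFrame:
    """Apply stored (mean, sd) to a raw-scale table of prediction inputs."""
    out = df.copy()
    for c, (mean, sd) in params.items():
        if c in out.columns:
            out[c] = (out[c].to_numpy(dtype=float) - mean) / sd
    return out


def de_standardize(values, column: str, params: dict[str, tuple[float, float]]):
    mean, sd = params[column]
    return np.asarray(values, dtype=float) * sd + mean
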