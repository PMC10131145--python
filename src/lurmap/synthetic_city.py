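"""Synthetic metropolis, measurement campaign and ground-truth pollutant generator.

The downstream modelling stages (QC, buffer predictors, mixed-effects LUR,
cross-validation, exposure surfaces, inequality analysis) need a city with
the layer inventory of a real LUR study — roads by class, land-use and NDVI
rasters, elevation, population zones, amenity points, an airport — plus a
one-year weekly meteorology with two seasonal regimes and a fixed/rotating
sampling design.  Everything here is a pure function of ``(config, seed)``
so the whole pipeline is testable without any external data.

The emulated campaign follows a West African dry-season pattern: a
"harmattan" regime (November–February) with no rainfall, lower relative
humidity and wind speed, and a roughly 4-fold elevation of fine-particle
mass (2-fold for black carbon) relative to the rest of the year.  Pollutant
fields are generated from a linear mixed model on standardized predictors —
log-linear for PM2.5 (right-skewed, strictly positive) and linear with a
floor at zero for BC absorbance — with crossed random intercepts for site
and week, so that the fitting stage has a well-defined truth to recover.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, Point, Polygon, box

from .geo import Grid, write_geojson, read_geojson

# ---------------------------------------------------------------------------
# Season calendar
# ---------------------------------------------------------------------------

HARMATTAN_MONTHS = (11, 12, 1, 2)
_MONTH_DAYS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)  # nominal year
_MONTH_END = np.cumsum(_MONTH_DAYS)

ROAD_CLASSES = ("major", "secondary", "minor")
LANDUSE_CLASSES = ("CBI", "informal_residential", "formal_residential", "other")
LANDUSE_CODE = {name: i for i, name in enumerate(LANDUSE_CLASSES)}
AMENITY_KINDS = ("bus_stop", "bus_terminal", "restaurant", "shopping_center")
STRATA = ("peri-urban", "CBI", "low-density residential", "high-density residential")


@dataclass(frozen=True)
class SeasonCalendar:
    """Maps calendar months to the two seasonal regimes."""

    harmattan_months: tuple[int, ...] = HARMATTAN_MONTHS

    def season_of_month(self, month: int) -> str:
        if not (1 <= int(month) <= 12):
            raise ValueError(f"invalid month {month!r}")
        return "harmattan" if int(month) in self.harmattan_months else "non_harmattan"

    def month_of_week(self, week_index: int) -> int:
        """Calendar month of the midpoint day of a 7-day week in a nominal year."""
        if week_index < 1:
            raise ValueError("week_index starts at 1")
        mid_day = 7 * (week_index - 1) + 4
        mid_day = ((mid_day - 1) % 365) + 1
        return int(np.searchsorted(_MONTH_END, mid_day, side="left") + 1)

    def season_of_week(self, week_index: int) -> str:
        return self.season_of_month(self.month_of_week(week_index))

    def weeks_per_season(self, n_weeks: int = 52) -> dict[str, int]:
        counts = {"harmattan": 0, "non_harmattan": 0}
        for w in range(1, n_weeks + 1):
            counts[self.season_of_week(w)] += 1
        return counts


DEFAULT_CALENDAR = SeasonCalendar()


# ---------------------------------------------------------------------------
# City scene
# ---------------------------------------------------------------------------


@dataclass
class SceneConfig:
    """Parameters of the synthetic metropolis.

    The defaults produce a ~12 km metropolis with a centre-to-periphery
    gradient in population density, greenness and local-street density,
    overlaid with idiosyncratic structure in every layer: multi-lane
    arterial corridors (major roads), connector chords and inner rings
    (secondary), outer rings and centre-biased local streets (minor),
    patchy land-use classes, and smooth NDVI / population noise fields.
    """

    extent: tuple[float, float, float, float] = (0.0, 0.0, 12000.0, 12000.0)
    landuse_cellsize: float = 20.0
    ndvi_cellsize: float = 30.0
    elevation_cellsize: float = 90.0
    n_radial_roads: int = 24
    ring_radii_fractions: tuple[float, ...] = (0.15, 0.35, 0.6, 0.85)
    n_local_roads: int = 60
    n_rivers: int = 8
    ndvi_core: float = 0.10
    ndvi_periphery: float = 0.42
    ndvi_noise_sd: float = 0.22
    cbi_radius_fraction: float = 0.12
    informal_radius_fraction: float = 0.35
    formal_radius_fraction: float = 0.68
    landuse_boundary_jitter: float = 1.00
    pop_zone_size: float = 1000.0
    pop_peak: float = 25000.0  # people/km^2 at the core
    pop_scale_fraction: float = 0.45
    amenity_counts: dict[str, int] = field(
        default_factory=lambda: {
            "bus_stop": 220,
            "bus_terminal": 45,
            "restaurant": 160,
            "shopping_center": 50,
        }
    )
    elevation_base: float = 20.0
    elevation_relief: float = 30.0
    elevation_noise_sd: float = 40.0

    def validate(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("extent must have positive width and height")
        for name in ("landuse_cellsize", "ndvi_cellsize", "elevation_cellsize"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CityScene:
    """All spatial layers of a (synthetic or real) metropolis in one projected frame."""

    extent: tuple[float, float, float, float]
    roads: list[tuple[LineString, str]]
    rivers: list[LineString]
    landuse: Grid
    ndvi: Grid
    elevation: Grid
    population_zones: list[tuple[Polygon, float]]
    amenities: list[tuple[Point, str]]
    airport: Point

    @property
    def center(self) -> tuple[float, float]:
        xmin, ymin, xmax, ymax = self.extent
        return ((xmin + xmax) / 2.0, (ymin + ymax) / 2.0)

    @property
    def rmax(self) -> float:
        xmin, ymin, xmax, ymax = self.extent
        return min(xmax - xmin, ymax - ymin) / 2.0

    def roads_of_class(self, cls: str) -> list[LineString]:
        if cls not in ROAD_CLASSES:
            raise ValueError(f"unknown road class {cls!r}")
        return [g for g, c in self.roads if c == cls]

    def amenity_points(self, kind: str) -> list[Point]:
        if kind not in AMENITY_KINDS:
            raise ValueError(f"unknown amenity kind {kind!r}")
        return [g for g, k in self.amenities if k == kind]


def _ring(cx: float, cy: float, radius: float, n: int = 96) -> LineString:
    ang = np.linspace(0.0, 2.0 * np.pi, n + 1)
    return LineString(np.c_[cx + radius * np.cos(ang), cy + radius * np.sin(ang)])


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma_cells: float) -> np.ndarray:
    """Unit-variance smooth Gaussian random field."""
    white = rng.standard_normal(shape)
    f = gaussian_filter(white, sigma=sigma_cells, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _radius_fraction_grid(grid: Grid, cx: float, cy: float, rmax: float) -> np.ndarray:
    xc = grid.x_centers()
    yc = grid.y_centers()
    return np.hypot(xc[None, :] - cx, yc[:, None] - cy) / rmax


def generate_city(config: SceneConfig | None = None, seed: int = 0) -> CityScene:
    """Generate a deterministic synthetic metropolis from ``(config, seed)``."""
    config = config or SceneConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = config.extent
    cx, cy = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
    rmax = min(xmax - xmin, ymax - ymin) / 2.0
    frame = box(xmin, ymin, xmax, ymax)

    # --- road network: cross-city arterials (major) + radial spokes and inner
    # rings (secondary) + outer rings and local streets (minor)
    roads: list[tuple[LineString, str]] = []
    n_rad = config.n_radial_roads
    if n_rad > 0:
        # arterials: N-S and E-W highway corridors at offsets from the centre;
        # each corridor is a bundle of parallel carriageways, so its buffered
        # length reads consistently across the 50-500 m radii
        for axis in ("ns",) * 6 + ("ew",) * 6:
            off = rng.uniform(0.08, 0.80) * rmax * rng.choice([-1.0, 1.0])
            spread = rng.uniform(50.0, 110.0)
            for lane_off in (-2 * spread, -spread, 0.0, spread, 2 * spread):
                o = off + lane_off
                if axis == "ns":
                    seg = LineString([(cx + o, ymin), (cx + o, ymax)])
                else:
                    seg = LineString([(xmin, cy + o), (xmax, cy + o)])
                roads.append((seg, "major"))
        # connector roads: chords with midpoints spread over the whole extent
        for i in range(n_rad):
            mx = rng.uniform(xmin, xmax)
            my = rng.uniform(ymin, ymax)
            ang2 = rng.uniform(0, 2 * np.pi)
            half = rng.uniform(0.15, 0.35) * rmax
            seg = LineString(
                [(mx - half * np.cos(ang2), my - half * np.sin(ang2)),
                 (mx + half * np.cos(ang2), my + half * np.sin(ang2))]
            ).intersection(frame)
            if not seg.is_empty:
                roads.append((seg, "secondary"))
    for k, f in enumerate(config.ring_radii_fractions):
        ring = _ring(cx, cy, f * rmax).intersection(frame)
        if ring.is_empty:
            continue
        cls = "secondary" if k < 2 else "minor"
        geoms = getattr(ring, "geoms", [ring])
        for g in geoms:
            roads.append((LineString(g.coords), cls))
    for _ in range(config.n_local_roads):
        r = rmax * rng.random() ** 1.5
        ang = rng.uniform(0, 2 * np.pi)
        x0 = cx + r * np.cos(ang)
        y0 = cy + r * np.sin(ang)
        length = rng.uniform(200.0, 800.0)
        ang2 = rng.uniform(0, 2 * np.pi)
        seg = LineString(
            [(x0, y0), (x0 + length * np.cos(ang2), y0 + length * np.sin(ang2))]
        ).intersection(frame)
        if not seg.is_empty and seg.length > 0:
            roads.append((seg, "minor"))

    # --- rivers: gentle sinusoids crossing the extent
    rivers: list[LineString] = []
    for i in range(config.n_rivers):
        y_base = rng.uniform(ymin + 0.2 * (ymax - ymin), ymin + 0.8 * (ymax - ymin))
        xs = np.linspace(xmin, xmax, 60)
        amp = rng.uniform(0.03, 0.08) * (ymax - ymin)
        phase = rng.uniform(0, 2 * np.pi)
        ys = y_base + amp * np.sin(2 * np.pi * xs / (xmax - xmin) * rng.uniform(4.0, 9.0) + phase)
        ys = np.clip(ys, ymin, ymax)
        rivers.append(LineString(np.c_[xs, ys]))

    # --- land use raster: a development-intensity score (radial trend plus a
    # dominant idiosyncratic patch field) thresholded into the four classes
    nlu_y = int(round((ymax - ymin) / config.landuse_cellsize))
    nlu_x = int(round((xmax - xmin) / config.landuse_cellsize))
    landuse = Grid(np.zeros((nlu_y, nlu_x)), xmin, ymin, config.landuse_cellsize)
    rfrac = _radius_fraction_grid(landuse, cx, cy, rmax)
    jitter = config.landuse_boundary_jitter * _smooth_field(rng, rfrac.shape, sigma_cells=4.5)
    rj = 0.3 * rfrac + jitter
    codes = np.full(rfrac.shape, LANDUSE_CODE["other"], dtype=float)
    q_cbi, q_inf, q_form = np.quantile(
        rj, [config.cbi_radius_fraction, config.informal_radius_fraction,
             config.formal_radius_fraction]
    )
    codes[rj < q_form] = LANDUSE_CODE["formal_residential"]
    codes[rj < q_inf] = LANDUSE_CODE["informal_residential"]
    codes[rj < q_cbi] = LANDUSE_CODE["CBI"]
    landuse.values = codes

    # --- NDVI raster: green periphery, grey core, smooth texture
    nnd_y = int(round((ymax - ymin) / config.ndvi_cellsize))
    nnd_x = int(round((xmax - xmin) / config.ndvi_cellsize))
    ndvi = Grid(np.zeros((nnd_y, nnd_x)), xmin, ymin, config.ndvi_cellsize)
    rfr = _radius_fraction_grid(ndvi, cx, cy, rmax)
    base = config.ndvi_core + (config.ndvi_periphery - config.ndvi_core) * np.clip(rfr, 0, 1)
    noise = config.ndvi_noise_sd * _smooth_field(rng, rfr.shape, sigma_cells=30.0)
    ndvi.values = np.clip(base + noise, -1.0, 1.0)

    # --- elevation raster: gentle tilt plus smooth relief
    nel_y = max(int(round((ymax - ymin) / config.elevation_cellsize)), 1)
    nel_x = max(int(round((xmax - xmin) / config.elevation_cellsize)), 1)
    elevation = Grid(np.zeros((nel_y, nel_x)), xmin, ymin, config.elevation_cellsize)
    xc = (elevation.x_centers() - xmin) / (xmax - xmin)
    yc = (elevation.y_centers() - ymin) / (ymax - ymin)
    tilt = config.elevation_relief * (0.6 * xc[None, :] + 0.4 * yc[:, None])
    relief = config.elevation_noise_sd * _smooth_field(rng, (nel_y, nel_x), sigma_cells=2.5)
    elevation.values = config.elevation_base + tilt + relief

    # --- population zones: square tiles; density = radial decay times a
    # spatially smooth lognormal field (smooth at the buffer scale, so the
    # buffered density at 50 m and 500 m read nearly the same surface)
    zones: list[tuple[Polygon, float]] = []
    zs = config.pop_zone_size
    nzy = int(round((ymax - ymin) / zs))
    nzx = int(round((xmax - xmin) / zs))
    tile_noise = _smooth_field(rng, (nzy, nzx), sigma_cells=0.9)
    for iy in range(nzy):
        for ix in range(nzx):
            x0 = xmin + ix * zs
            y0 = ymin + iy * zs
            zx, zy = x0 + zs / 2, y0 + zs / 2
            rf = math.hypot(zx - cx, zy - cy) / rmax
            dens = config.pop_peak * math.exp(-rf / config.pop_scale_fraction)
            dens *= float(np.exp(1.0 * tile_noise[nzy - 1 - iy, ix]))
            zones.append((box(x0, y0, x0 + zs, y0 + zs), dens))

    # --- amenities: centre-biased point layers
    amenities: list[tuple[Point, str]] = []
    for kind in AMENITY_KINDS:
        n = config.amenity_counts.get(kind, 0)
        r = rmax * rng.random(n) ** 0.55
        ang = rng.uniform(0, 2 * np.pi, n)
        px = np.clip(cx + r * np.cos(ang), xmin, xmax)
        py = np.clip(cy + r * np.sin(ang), ymin, ymax)
        amenities.extend((Point(x, y), kind) for x, y in zip(px, py))

    ap_ang = rng.uniform(0, 2 * np.pi)
    airport = Point(cx + 0.9 * rmax * np.cos(ap_ang), cy + 0.9 * rmax * np.sin(ap_ang))

    return CityScene(
        extent=config.extent,
        roads=roads,
        rivers=rivers,
        landuse=landuse,
        ndvi=ndvi,
        elevation=elevation,
        population_zones=zones,
        amenities=amenities,
        airport=airport,
    )


# ---------------------------------------------------------------------------
# Weekly meteorology with two seasonal regimes
# ---------------------------------------------------------------------------

MET_COLUMNS = (
    "week_index",
    "month",
    "season",
    "temperature",
    "relative_humidity",
    "wind_speed",
    "wind_direction",
    "rainfall_presence",
    "mixing_layer_depth",
    "water_vapor_mixing_ratio",
    "solar_radiation",
)


@dataclass(frozen=True)
class RegimeParams:
    rh_mean: float
    rh_sd: float
    wind_mean: float
    wind_sd: float
    temp_mean: float
    temp_sd: float
    rain_prob: float
    mld_mean: float
    mld_sd: float
    wvmr_mean: float
    wvmr_sd: float
    solar_mean: float
    solar_sd: float
    wind_dir_mean: float
    wind_dir_sd: float


@dataclass(frozen=True)
class MetConfig:
    """Two-regime weekly meteorology.

    Defaults emulate the dry-season contrast: no rainfall, lower relative
    humidity and wind speed, shallower mixing layers during harmattan.
    """

    harmattan: RegimeParams = RegimeParams(
        rh_mean=60.0, rh_sd=6.0, wind_mean=1.8, wind_sd=0.35, temp_mean=29.0,
        temp_sd=1.1, rain_prob=0.0, mld_mean=450.0, mld_sd=80.0,
        wvmr_mean=0.012, wvmr_sd=0.0015, solar_mean=210.0, solar_sd=25.0,
        wind_dir_mean=45.0, wind_dir_sd=15.0,
    )
    non_harmattan: RegimeParams = RegimeParams(
        rh_mean=80.0, rh_sd=5.0, wind_mean=3.2, wind_sd=0.5, temp_mean=27.0,
        temp_sd=1.1, rain_prob=0.65, mld_mean=650.0, mld_sd=100.0,
        wvmr_mean=0.017, wvmr_sd=0.002, solar_mean=180.0, solar_sd=25.0,
        wind_dir_mean=225.0, wind_dir_sd=30.0,
    )

    def validate(self) -> None:
        for name in ("harmattan", "non_harmattan"):
            p = getattr(self, name)
            if not (0.0 <= p.rh_mean <= 100.0):
                raise ValueError(f"{name}: rh_mean {p.rh_mean} outside [0, 100]")
            if p.wind_mean < 0 or not (0.0 <= p.rain_prob <= 1.0):
                raise ValueError(f"{name}: invalid wind or rainfall parameters")
            for v in (p.rh_sd, p.wind_sd, p.temp_sd, p.mld_sd, p.wvmr_sd, p.solar_sd):
                if not np.isfinite(v) or v < 0:
                    raise ValueError(f"{name}: non-finite or negative spread parameter")


def generate_meteorology(
    calendar: SeasonCalendar = DEFAULT_CALENDAR,
    config: MetConfig | None = None,
    seed: int = 0,
    n_weeks: int = 52,
) -> pd.DataFrame:
    """Simulate one weekly meteorology record per campaign week."""
    config = config or MetConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for w in range(1, n_weeks + 1):
        month = calendar.month_of_week(w)
        season = calendar.season_of_month(month)
        p = config.harmattan if season == "harmattan" else config.non_harmattan
        rows.append(
            {
                "week_index": w,
                "month": month,
                "season": season,
                "temperature": rng.normal(p.temp_mean, p.temp_sd),
                "relative_humidity": float(np.clip(rng.normal(p.rh_mean, p.rh_sd), 0.0, 100.0)),
                "wind_speed": float(max(rng.normal(p.wind_mean, p.wind_sd), 0.1)),
                "wind_direction": float(rng.normal(p.wind_dir_mean, p.wind_dir_sd) % 360.0),
                "rainfall_presence": int(rng.random() < p.rain_prob),
                "mixing_layer_depth": float(max(rng.normal(p.mld_mean, p.mld_sd), 50.0)),
                "water_vapor_mixing_ratio": float(max(rng.normal(p.wvmr_mean, p.wvmr_sd), 1e-4)),
                "solar_radiation": float(max(rng.normal(p.solar_mean, p.solar_sd), 0.0)),
            }
        )
    return pd.DataFrame(rows, columns=list(MET_COLUMNS))


# ---------------------------------------------------------------------------
# Sampling design
# ---------------------------------------------------------------------------


@dataclass
class SamplingConfig:
    n_fixed: int = 10
    n_rotating: int = 136
    n_weeks: int = 52
    candidate_spacing: float = 250.0
    margin: float = 200.0
    periurban_radius_fraction: float = 0.72


@dataclass
class SamplingDesign:
    """Fixed + rotating monitoring sites with their assigned campaign weeks."""

    sites: pd.DataFrame  # columns: site_id, x, y, type, stratum
    assigned_weeks: dict[str, list[int]]

    def records(self) -> pd.DataFrame:
        rows = [
            {"site_id": sid, "week_index": w}
            for sid in self.sites["site_id"]
            for w in self.assigned_weeks[sid]
        ]
        return pd.DataFrame(rows)

    @property
    def n_records(self) -> int:
        return sum(len(v) for v in self.assigned_weeks.values())


class DesignError(ValueError):
    """More sites requested than candidate locations available."""


def _allocate(total: int, counts: list[int], rng: np.random.Generator) -> list[int]:
    """Largest-remainder proportional allocation with >=1 per non-empty stratum."""
    counts = np.asarray(counts, dtype=float)
    nonzero = counts > 0
    alloc = np.zeros(len(counts), dtype=int)
    if total >= nonzero.sum():
        alloc[nonzero] = 1
    remaining = total - alloc.sum()
    if remaining > 0:
        share = counts / counts.sum() * remaining
        base = np.floor(share).astype(int)
        alloc += base
        rem = remaining - base.sum()
        order = np.argsort(-(share - base))
        for i in range(rem):
            alloc[order[i % len(order)]] += 1
    # never allocate more than available
    over = alloc - counts.astype(int)
    while (over > 0).any():
        i = int(np.argmax(over))
        alloc[i] = int(counts[i])
        deficit = int(over[over > 0].sum())
        room = np.where(alloc < counts)[0]
        for j in room[:deficit]:
            alloc[j] += 1
        over = alloc - counts.astype(int)
    return alloc.tolist()


def design_sampling(
    scene: CityScene, config: SamplingConfig | None = None, seed: int = 0
) -> SamplingDesign:
    """Stratified random fixed/rotating site selection across land-use strata."""
    config = config or SamplingConfig()
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = scene.extent
    cx, cy = scene.center
    xs = np.arange(xmin + config.margin, xmax - config.margin + 1e-9, config.candidate_spacing)
    ys = np.arange(ymin + config.margin, ymax - config.margin + 1e-9, config.candidate_spacing)
    cand_x, cand_y = [a.ravel() for a in np.meshgrid(xs, ys)]
    rfrac = np.hypot(cand_x - cx, cand_y - cy) / scene.rmax

    strata = []
    for x, y, rf in zip(cand_x, cand_y, rfrac):
        if rf > config.periurban_radius_fraction:
            strata.append("peri-urban")
            continue
        code = scene.landuse.value_at(x, y)
        name = LANDUSE_CLASSES[int(code)]
        strata.append(
            {
                "CBI": "CBI",
                "informal_residential": "high-density residential",
                "formal_residential": "low-density residential",
                "other": "peri-urban",
            }[name]
        )
    strata = np.array(strata)

    n_total = config.n_fixed + config.n_rotating
    if n_total > len(cand_x):
        raise DesignError(
            f"requested {n_total} sites but only {len(cand_x)} candidate locations"
        )

    stratum_idx = {s: np.where(strata == s)[0] for s in STRATA}
    counts = [len(stratum_idx[s]) for s in STRATA]
    picked: dict[str, np.ndarray] = {}
    fixed_alloc = _allocate(config.n_fixed, counts, rng)
    rows = []
    used = set()

    def draw(stratum: str, k: int) -> list[int]:
        pool = [i for i in stratum_idx[stratum] if i not in used]
        if k > len(pool):
            raise DesignError(f"stratum {stratum!r} has only {len(pool)} free candidates")
        chosen = rng.choice(len(pool), size=k, replace=False)
        out = [pool[int(c)] for c in chosen]
        used.update(out)
        return out

    fid = 1
    for s, k in zip(STRATA, fixed_alloc):
        for i in draw(s, k):
            rows.append(
                {"site_id": f"F{fid:02d}", "x": cand_x[i], "y": cand_y[i], "type": "fixed", "stratum": s}
            )
            fid += 1
    remaining_counts = [len([i for i in stratum_idx[s] if i not in used]) for s in STRATA]
    rot_alloc = _allocate(config.n_rotating, remaining_counts, rng)
    rid = 1
    for s, k in zip(STRATA, rot_alloc):
        for i in draw(s, k):
            rows.append(
                {"site_id": f"R{rid:03d}", "x": cand_x[i], "y": cand_y[i], "type": "rotating", "stratum": s}
            )
            rid += 1

    sites = pd.DataFrame(rows, columns=["site_id", "x", "y", "type", "stratum"])
    all_weeks = list(range(1, config.n_weeks + 1))
    assigned: dict[str, list[int]] = {}
    for _, r in sites.iterrows():
        if r["type"] == "fixed":
            assigned[r["site_id"]] = list(all_weeks)
        else:
            assigned[r["site_id"]] = [int(rng.integers(1, config.n_weeks + 1))]
    return SamplingDesign(sites=sites, assigned_weeks=assigned)


# ---------------------------------------------------------------------------
# Ground truth and concentration simulation
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Generating model: fixed effects on standardized predictors + crossed
    random intercepts (site, week) + residual noise, with an additive seasonal
    shift on the linear-predictor scale."""

    alpha: float
    beta: dict[str, float]
    sigma2_site: float
    sigma2_week: float
    sigma2_eps: float
    harmattan_shift: float = 0.0
    link: str = "log"  # "log" (PM2.5, ug/m3) or "identity" (BC, 1e-5/m)

    def __post_init__(self) -> None:
        for name in ("sigma2_site", "sigma2_week", "sigma2_eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.link not in ("log", "identity"):
            raise ValueError("link must be 'log' or 'identity'")


def default_truth_pm25() -> GroundTruth:
    """Generating truth for log-PM2.5.

    Standardized slopes follow the magnitudes a LUR of this kind reports
    (greenness negative, population density and major-road length positive);
    the seasonal shift log(4) yields a 4-fold harmattan elevation of the
    mean.  The residual is dominated by per-sample noise (weekly gravimetric
    measurement and micro-environment variation), with a smaller shared
    weekly component and a spatially well-specified mean (no extra
    site-level residual), so the fixed effects explain about half of the
    log-concentration variance.
    """
    return GroundTruth(
        alpha=3.02,
        beta={
            "ndvi_100": -0.12,
            "population_density_50": 0.12,
            "major_road_length_500": 0.07,
        },
        sigma2_site=0.0,
        sigma2_week=0.004,
        sigma2_eps=0.032,
        harmattan_shift=math.log(4.0),
        link="log",
    )


def default_truth_bc() -> GroundTruth:
    """Generating truth for BC absorbance (natural scale, 1e-5/m units).

    The harmattan shift of +5.7 doubles the seasonal mean (11.4 vs 5.7).
    """
    return GroundTruth(
        alpha=5.7,
        beta={
            "major_road_length_100": 1.36,
            "secondary_road_length_200": 0.93,
            "ndvi_100": -0.78,
        },
        sigma2_site=0.25,
        sigma2_week=0.30,
        sigma2_eps=1.45,
        harmattan_shift=5.7,
        link="identity",
    )


def simulate_concentrations(
    X: pd.DataFrame,
    design: SamplingDesign,
    met: pd.DataFrame,
    truth: GroundTruth,
    seed: int = 0,
    calendar: SeasonCalendar = DEFAULT_CALENDAR,
) -> pd.DataFrame:
    """Simulate one pollutant series over the site-week records of a design.

    ``X`` must contain one row per (site_id, week_index) record with the
    standardized predictor columns named in ``truth.beta`` (standardization
    on the simulation population).  Returns columns
    ``site_id, week_index, month, season, value`` with PM2.5 generated as
    ``exp(linear predictor)`` and BC on the natural scale floored at zero.
    """
    missing = [c for c in truth.beta if c not in X.columns]
    if missing:
        raise KeyError(f"predictors named in truth.beta absent from X: {missing}")
    if not {"site_id", "week_index"}.issubset(X.columns):
        raise KeyError("X must carry site_id and week_index columns")

    rng = np.random.default_rng(seed)
    df = X.copy()
    df["month"] = df["week_index"].map(calendar.month_of_week)
    df["season"] = df["month"].map(calendar.season_of_month)

    site_ids = pd.Index(sorted(design.sites["site_id"]))
    week_ids = pd.Index(sorted(df["week_index"].unique()))
    b_site = pd.Series(rng.normal(0.0, math.sqrt(truth.sigma2_site), len(site_ids)), index=site_ids)
    b_week = pd.Series(rng.normal(0.0, math.sqrt(truth.sigma2_week), len(week_ids)), index=week_ids)
    eps = rng.normal(0.0, math.sqrt(truth.sigma2_eps), len(df))

    beta_cols = list(truth.beta)
    lin = (
        truth.alpha
        + df[beta_cols].to_numpy() @ np.array([truth.beta[c] for c in beta_cols])
        + truth.harmattan_shift * (df["season"] == "harmattan").to_numpy(dtype=float)
        + b_site.reindex(df["site_id"]).to_numpy()
        + b_week.reindex(df["week_index"]).to_numpy()
        + eps
    )
    value = np.exp(lin) if truth.link == "log" else np.maximum(lin, 0.0)
    out = df[["site_id", "week_index", "month", "season"]].copy()
    out["value"] = value
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class QCSimConfig:
    """Instrument-failure rates so the QC filters downstream have work to do."""

    runtime_fail_rate: float = 0.04
    flow_fail_rate: float = 0.02
    continuous_cf: float = 1.25  # gravimetric / continuous (optical sensor reads low)
    continuous_noise_sd: float = 0.05
    continuous_missing_rate: float = 0.01


def simulate_measurement_table(
    X: pd.DataFrame,
    design: SamplingDesign,
    met: pd.DataFrame,
    truth_pm25: GroundTruth,
    truth_bc: GroundTruth,
    seed: int = 0,
    qc: QCSimConfig | None = None,
    calendar: SeasonCalendar = DEFAULT_CALENDAR,
) -> pd.DataFrame:
    """Full raw campaign table: both pollutants plus simulated QC metadata.

    Gravimetric PM2.5 and filter-based BC absorbance go missing together when
    the sampler runtime collapses; the co-located continuous monitor reads low
    by the configured correction factor and survives most failures.
    """
    qc = qc or QCSimConfig()
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=3)
    pm = simulate_concentrations(X, design, met, truth_pm25, seed=int(sub[0]), calendar=calendar)
    bc = simulate_concentrations(X, design, met, truth_bc, seed=int(sub[1]), calendar=calendar)

    n = len(pm)
    r2 = np.random.default_rng(int(sub[2]))
    runtime = r2.uniform(0.85, 1.0, n)
    bad_rt = r2.random(n) < qc.runtime_fail_rate
    runtime[bad_rt] = r2.uniform(0.30, 0.745, bad_rt.sum())
    flow = r2.normal(1.0, 0.02, n)
    bad_flow = r2.random(n) < qc.flow_fail_rate
    flow[bad_flow] = 1.0 + r2.choice([-1.0, 1.0], bad_flow.sum()) * r2.uniform(0.12, 0.2, bad_flow.sum())

    table = pm[["site_id", "week_index", "month", "season"]].copy()
    grav = pm["value"].to_numpy().copy()
    grav[runtime < 0.75] = np.nan
    cont = pm["value"].to_numpy() / qc.continuous_cf
    cont = cont * np.exp(r2.normal(0.0, qc.continuous_noise_sd, n))
    cont[r2.random(n) < qc.continuous_missing_rate] = np.nan
    absb = bc["value"].to_numpy().copy()
    absb[runtime < 0.75] = np.nan

    table["pm25_gravimetric"] = grav
    table["pm25_continuous_mean"] = cont
    table["bc_absorbance"] = absb
    table["runtime_fraction"] = runtime
    table["mean_flow"] = flow
    return table


# ---------------------------------------------------------------------------
# Synthetic census enumeration areas (for the exposure/inequality stage)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EAConfig:
    """Synthetic enumeration areas over the urban core.

    SES (median log equivalized household consumption) rises with distance
    from the core and with greenness, i.e. it is negatively coupled to the
    pollution field the generating truths produce (which peaks centrally).
    """

    ea_size: float = 200.0
    core_radius_fraction: float = 0.55
    pop_mean: float = 775.0
    pop_sd: float = 150.0
    ses_base: float = 7.0
    ses_radial_slope: float = 1.2
    ses_ndvi_slope: float = 1.0
    ses_popdens_slope: float = -0.7  # per sd of log local population density
    ses_noise_sd: float = 0.18
    edu_logit_slope: float = 1.5


def generate_enumeration_areas(
    scene: CityScene, config: EAConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Tile the urban core with square EAs carrying population, SES and education."""
    config = config or EAConfig()
    rng = np.random.default_rng(seed)
    cx, cy = scene.center
    half = config.core_radius_fraction * scene.rmax
    half = math.floor(half / config.ea_size) * config.ea_size
    edges = np.arange(-half, half + 1e-9, config.ea_size)
    rows = []
    ndvi = scene.ndvi

    def zone_density(x: float, y: float) -> float:
        for poly, dens in scene.population_zones:
            if poly.covers(Point(x, y)):
                return dens
        return 0.0

    centroids = [
        (cx + x0 + config.ea_size / 2, cy + y0 + config.ea_size / 2)
        for y0 in edges[:-1] for x0 in edges[:-1]
    ]
    logdens = np.log(np.maximum([zone_density(*c) for c in centroids], 1.0))
    ld_mean, ld_sd = logdens.mean(), logdens.std() or 1.0

    for k, ((ex, ey), ld) in enumerate(zip(centroids, logdens), start=1):
        x0, y0 = ex - config.ea_size / 2, ey - config.ea_size / 2
        poly = box(x0, y0, x0 + config.ea_size, y0 + config.ea_size)
        rf = math.hypot(ex - cx, ey - cy) / scene.rmax
        ses = (
            config.ses_base
            + config.ses_radial_slope * rf
            + config.ses_ndvi_slope * ndvi.value_at(ex, ey)
            + config.ses_popdens_slope * (ld - ld_mean) / ld_sd
            + rng.normal(0.0, config.ses_noise_sd)
        )
        z = config.edu_logit_slope * (ses - config.ses_base - 0.6) + rng.normal(0.0, 0.3)
        edu = 1.0 / (1.0 + math.exp(-z))
        pop = max(50.0, rng.normal(config.pop_mean, config.pop_sd))
        rows.append(
            {
                "ea_id": f"EA{k:04d}",
                "geometry": poly,
                "x": ex,
                "y": ey,
                "population": pop,
                "ses": ses,
                "post_secondary_share": edu,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scene / table I/O
# ---------------------------------------------------------------------------


def write_scene(scene: CityScene, outdir) -> None:
    """Write vector layers as GeoJSON, rasters as ESRI ASCII grids."""
    os.makedirs(outdir, exist_ok=True)
    write_geojson(
        os.path.join(outdir, "roads.geojson"),
        [g for g, _ in scene.roads],
        [{"class": c} for _, c in scene.roads],
    )
    write_geojson(os.path.join(outdir, "rivers.geojson"), scene.rivers)
    write_geojson(
        os.path.join(outdir, "amenities.geojson"),
        [g for g, _ in scene.amenities],
        [{"kind": k} for _, k in scene.amenities],
    )
    write_geojson(
        os.path.join(outdir, "population_zones.geojson"),
        [g for g, _ in scene.population_zones],
        [{"density": d} for _, d in scene.population_zones],
    )
    write_geojson(os.path.join(outdir, "airport.geojson"), [scene.airport])
    scene.landuse.write_ascii(os.path.join(outdir, "landuse.asc"))
    scene.ndvi.write_ascii(os.path.join(outdir, "ndvi.asc"))
    scene.elevation.write_ascii(os.path.join(outdir, "elevation.asc"))
    with open(os.path.join(outdir, "scene.json"), "w") as fh:
        json.dump({"extent": list(scene.extent)}, fh)


def read_scene(indir) -> CityScene:
    with open(os.path.join(indir, "scene.json")) as fh:
        meta = json.load(fh)
    roads_g, roads_p = read_geojson(os.path.join(indir, "roads.geojson"))
    rivers_g, _ = read_geojson(os.path.join(indir, "rivers.geojson"))
    amen_g, amen_p = read_geojson(os.path.join(indir, "amenities.geojson"))
    zone_g, zone_p = read_geojson(os.path.join(indir, "population_zones.geojson"))
    airport_g, _ = read_geojson(os.path.join(indir, "airport.geojson"))
    return CityScene(
        extent=tuple(meta["extent"]),
        roads=[(g, p["class"]) for g, p in zip(roads_g, roads_p)],
        rivers=rivers_g,
        landuse=Grid.read_ascii(os.path.join(indir, "landuse.asc")),
        ndvi=Grid.read_ascii(os.path.join(indir, "ndvi.asc")),
        elevation=Grid.read_ascii(os.path.join(indir, "elevation.asc")),
        population_zones=[(g, p["density"]) for g, p in zip(zone_g, zone_p)],
        amenities=[(g, p["kind"]) for g, p in zip(amen_g, amen_p)],
        airport=airport_g[0],
    )
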