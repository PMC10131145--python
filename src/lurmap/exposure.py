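"""Prediction surfaces, enumeration-area overlay, and exposure-inequality
analysis.

Final models are applied to a regular 100 m grid: per-week fixed-effects
predictions per cell (log-PM2.5 exponentiated to μg/m³), averaged to
seasonal surfaces and a week-count-weighted annual surface.  Surfaces are
overlaid with census enumeration areas (EAs) carrying population and SES to
give per-EA means, population shares above the WHO annual PM2.5 guideline
and interim targets (5 / 15 / 25 / 35 μg/m³), SES-quintile contrasts tested
with one-way ANOVA and Tukey's HSD, and the education bivariate association.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from shapely import contains_xy

from .geo import Grid
from .features import (
    PredictorMatrix,
    PredictorRegistry,
    compute_spatial_features,
    weekly_temporal_features,
    apply_standardization,
)
from .lur import FittedLUR
from .synthetic_city import CityScene, SeasonCalendar, DEFAULT_CALENDAR


class ContractError(KeyError):
    """A continuous model term has no stored standardization parameter."""


@dataclass(frozen=True)
class ExposureThresholds:
    """WHO annual PM2.5 guideline and interim targets, μg/m³."""

    guideline: float = 5.0
    it3: float = 15.0
    it2: float = 25.0
    it1: float = 35.0

    def __post_init__(self) -> None:
        seq = (self.guideline, self.it3, self.it2, self.it1)
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise ValueError("thresholds must be strictly increasing")

    def as_dict(self) -> dict[str, float]:
        return {"guideline": self.guideline, "it3": self.it3,
                "it2": self.it2, "it1": self.it1}


@dataclass
class ExposureSurface:
    """Weekly/seasonal/annual prediction surfaces on a regular grid."""

    template: Grid  # geometry carrier; values unused
    weeks: list[int]
    weekly: np.ndarray  # (n_weeks, ny, nx)
    seasonal: dict[str, np.ndarray] = field(default_factory=dict)
    annual: np.ndarray | None = None

    def seasonal_grid(self, season: str) -> Grid:
        return Grid(self.seasonal[season], self.template.x0, self.template.y0,
                    self.template.cellsize)

    def annual_grid(self) -> Grid:
        return Grid(self.annual, self.template.x0, self.template.y0,
                    self.template.cellsize)


def grid_template(extent, cellsize: float = 100.0) -> Grid:
    xmin, ymin, xmax, ymax = extent
    nx = int(round((xmax - xmin) / cellsize))
    ny = int(round((ymax - ymin) / cellsize))
    return Grid(np.zeros((ny, nx)), xmin, ymin, cellsize)


def grid_cell_table(template: Grid) -> pd.DataFrame:
    """Cell-centre coordinate table in raster order (row-major, north first)."""
    xc = template.x_centers()
    yc = template.y_centers()
    X, Y = np.meshgrid(xc, yc)
    return pd.DataFrame(
        {"site_id": [f"cell{i}" for i in range(X.size)],
         "x": X.ravel(), "y": Y.ravel()}
    )


def compute_grid_features(
    scene: CityScene, fit: FittedLUR, registry: PredictorRegistry,
    cellsize: float = 100.0,
) -> tuple[Grid, pd.DataFrame]:
    """Spatial features at 100 m cell centres, restricted to the model's terms."""
    template = grid_template(scene.extent, cellsize)
    cells = grid_cell_table(template)
    spatial_terms = {c.base for c in _spatial_metas(fit, registry)}
    sub = registry.subset(spatial_terms) if spatial_terms else registry.subset([])
    feats = (
        compute_spatial_features(scene, cells, sub)
        if spatial_terms
        else cells[["site_id"]].copy()
    )
    return template, feats


def _spatial_metas(fit: FittedLUR, registry: PredictorRegistry):
    names = {e.name for e in registry.spatial()}

    class _M:
        def __init__(self, base):
            self.base = base

    out = []
    for t in fit.term_names:
        base = t
        for e in registry.spatial():
            if t == e.name or t.startswith(e.name + "_"):
                base = e.name
                break
        if base in names:
            out.append(_M(base))
    return out


def predict_surface(
    fit: FittedLUR,
    template: Grid,
    cell_features: pd.DataFrame,
    met: pd.DataFrame,
    registry: PredictorRegistry,
    weeks: list[int] | None = None,
    reference_month: int = 3,
) -> ExposureSurface:
    """Per-week fixed-effects prediction per grid cell.

    ``cell_features`` are raw-scale spatial features per cell; temporal
    predictors come from the meteorology table per week.  Standardization
    parameters stored on the fit are applied verbatim; a continuous term
    without one raises :class:`ContractError`.  Log-PM2.5 models are
    exponentiated to μg/m³.  A model with only temporal terms yields a
    spatially constant surface each week.
    """
    weeks = list(weeks) if weeks is not None else list(met["week_index"])
    temporal = weekly_temporal_features(met, registry, reference_month)
    temporal = temporal.set_index("week_index")

    spatial_terms = [t for t in fit.term_names if t in cell_features.columns]
    temporal_terms = [t for t in fit.term_names if t in temporal.columns]
    unknown = [
        t for t in fit.term_names if t not in spatial_terms + temporal_terms
    ]
    if unknown:
        raise ContractError(f"model terms without a feature source: {unknown}")
    continuous = set(fit.standardization)
    for t in fit.term_names:
        if t not in continuous and not (t.startswith("month_") or "presence" in t):
            raise ContractError(f"term {t!r} has no stored standardization parameter")

    cells_std = apply_standardization(cell_features, fit.standardization)
    spatial_part = np.zeros(len(cell_features))
    for t in spatial_terms:
        spatial_part += float(fit.params[t]) * cells_std[t].to_numpy(dtype=float)

    temporal_std = apply_standardization(temporal.reset_index(), fit.standardization)
    temporal_std = temporal_std.set_index("week_index")
    ny, nx = template.ny, template.nx
    weekly = np.empty((len(weeks), ny, nx))
    for i, w in enumerate(weeks):
        tpart = float(fit.params["intercept"])
        for t in temporal_terms:
            tpart += float(fit.params[t]) * float(temporal_std.loc[w, t])
        lin = spatial_part + tpart
        if fit.response == "log_pm25":
            lin = np.exp(lin)
        weekly[i] = lin.reshape(ny, nx)
    return ExposureSurface(template=template, weeks=weeks, weekly=weekly)


def seasonal_annual_means(
    surface: ExposureSurface, calendar: SeasonCalendar = DEFAULT_CALENDAR
) -> ExposureSurface:
    """Season means over each season's weeks; annual = week-count-weighted mean."""
    seasons = np.array([calendar.season_of_week(w) for w in surface.weeks])
    out: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for s in ("harmattan", "non_harmattan"):
        mask = seasons == s
        if not mask.any():
            raise ValueError(f"season {s!r} has zero predicted weeks")
        out[s] = surface.weekly[mask].mean(axis=0)
        counts[s] = int(mask.sum())
    total = sum(counts.values())
    surface.seasonal = out
    surface.annual = sum(out[s] * counts[s] for s in out) / total
    return surface


# ---------------------------------------------------------------------------
# Enumeration-area overlay
# ---------------------------------------------------------------------------


def ea_mean(grid: Grid, eas: pd.DataFrame, value_col: str = "mean_value",
            method: str = "cell_center") -> pd.DataFrame:
    """Per-EA mean of a surface.

    ``cell_center``: mean over cells whose centres fall inside the EA
    polygon, falling back to the single cell containing the EA centroid for
    EAs smaller than a cell.  ``area_weighted``: polygon-cell intersection
    areas as weights.  EAs outside the surface extent get NaN.
    """
    xc = grid.x_centers()
    yc = grid.y_centers()
    X, Y = np.meshgrid(xc, yc)
    xmin, ymin, xmax, ymax = grid.extent
    out = eas.copy()
    vals = []
    for _, row in eas.iterrows():
        poly = row["geometry"]
        if not (xmin <= poly.centroid.x <= xmax and ymin <= poly.centroid.y <= ymax):
            vals.append(np.nan)
            continue
        if method == "cell_center":
            bx0, by0, bx1, by1 = poly.bounds
            jm = (xc >= bx0 - grid.cellsize) & (xc <= bx1 + grid.cellsize)
            im = (yc >= by0 - grid.cellsize) & (yc <= by1 + grid.cellsize)
            Xs, Ys = X[np.ix_(im, jm)], Y[np.ix_(im, jm)]
            inside = contains_xy(poly, Xs.ravel(), Ys.ravel())
            if inside.any():
                vals.append(float(grid.values[np.ix_(im, jm)].ravel()[inside].mean()))
            else:
                vals.append(grid.value_at(poly.centroid.x, poly.centroid.y))
        elif method == "area_weighted":
            from shapely.geometry import box as _box

            bx0, by0, bx1, by1 = poly.bounds
            total_w = 0.0
            total_v = 0.0
            for i, y0 in enumerate(yc):
                if y0 < by0 - grid.cellsize or y0 > by1 + grid.cellsize:
                    continue
                for j, x0 in enumerate(xc):
                    if x0 < bx0 - grid.cellsize or x0 > bx1 + grid.cellsize:
                        continue
                    cell = _box(x0 - grid.cellsize / 2, y0 - grid.cellsize / 2,
                                x0 + grid.cellsize / 2, y0 + grid.cellsize / 2)
                    a = poly.intersection(cell).area
                    if a > 0:
                        total_w += a
                        total_v += a * grid.values[i, j]
            vals.append(total_v / total_w if total_w > 0 else np.nan)
        else:
            raise ValueError("method must be 'cell_center' or 'area_weighted'")
    out[value_col] = vals
    return out


# ---------------------------------------------------------------------------
# Population exposure and SES inequality
# ---------------------------------------------------------------------------


def population_exposure_cdf(
    eas: pd.DataFrame,
    thresholds: ExposureThresholds | None = None,
    value_col: str = "mean_value",
    strict: bool = True,
    curve_points: int = 200,
) -> dict:
    """Population share living in EAs with mean concentration above each
    threshold, plus the full cumulative curve.

    ``strict`` compares with ``>`` (share above the target); switchable to
    ``>=``.
    """
    thresholds = thresholds or ExposureThresholds()
    pop = eas["population"].to_numpy(dtype=float)
    conc = eas[value_col].to_numpy(dtype=float)
    total = pop.sum()
    if total <= 0:
        raise ValueError("zero total population")

    def share_above(t: float) -> float:
        mask = conc > t if strict else conc >= t
        return float(pop[mask].sum() / total)

    grid = np.linspace(0.0, max(conc.max() * 1.05, thresholds.it1 * 1.1), curve_points)
    return {
        "shares": {k: share_above(v) for k, v in thresholds.as_dict().items()},
        "thresholds": thresholds.as_dict(),
        "curve": pd.DataFrame({"concentration": grid,
                               "share_above": [share_above(t) for t in grid]}),
    }


def ses_quintiles(eas: pd.DataFrame, ses_col: str = "ses") -> pd.Series:
    """Rank-based SES quintiles, 1 = poorest; equal counts ±1; stable ties."""
    if len(eas) < 5:
        raise ValueError("need >= 5 EAs for quintiles")
    order = eas.sort_values([ses_col, "ea_id"], kind="mergesort").index
    labels = pd.Series(0, index=eas.index)
    for q, chunk in enumerate(np.array_split(np.asarray(order), 5), start=1):
        labels.loc[chunk] = q
    return labels.astype(int)


def inequality_tests(
    eas: pd.DataFrame, value_col: str = "mean_value", quintile_col: str = "quintile"
) -> dict:
    """One-way ANOVA across SES quintiles + Tukey HSD + per-quintile summaries."""
    groups = [
        g[value_col].to_numpy(dtype=float)
        for _, g in eas.groupby(quintile_col, sort=True)
    ]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every quintile needs >= 2 EAs")
    if all(np.std(g) == 0 for g in groups):
        raise ValueError("zero within-group variance everywhere: ANOVA degenerate")
    f_stat, p = stats.f_oneway(*groups)
    tukey = stats.tukey_hsd(*groups)
    qlabels = sorted(eas[quintile_col].unique())
    pairs = []
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            ci = tukey.confidence_interval()
            pairs.append(
                {
                    "group_a": qlabels[a],
                    "group_b": qlabels[b],
                    "mean_diff": float(np.mean(groups[a]) - np.mean(groups[b])),
                    "p_adj": float(tukey.pvalue[a, b]),
                    "ci_lo": float(ci.low[a, b]),
                    "ci_hi": float(ci.high[a, b]),
                }
            )
    summary = (
        eas.groupby(quintile_col)[value_col]
        .agg(
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
            mean="mean",
            n="count",
        )
        .reset_index()
    )
    return {
        "anova_f": float(f_stat),
        "anova_p": float(p),
        "tukey": pd.DataFrame(pairs),
        "summary": summary,
    }


def education_bivariate(
    eas: pd.DataFrame, value_col: str = "mean_value",
    edu_col: str = "post_secondary_share",
) -> dict:
    """Pearson correlation and OLS slope of EA concentration on education."""
    x = eas[edu_col].to_numpy(dtype=float)
    y = eas[value_col].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in education or concentration")
    lin = stats.linregress(x, y)
    return {"r": float(lin.rvalue), "slope": float(lin.slope),
            "intercept": float(lin.intercept), "p_value": float(lin.pvalue)}
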