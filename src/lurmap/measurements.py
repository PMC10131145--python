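"""Campaign QC rules, correction-factor gap-filling, season labels, and the
absorbance-to-elemental-carbon conversion.

The weekly measurement table carries gravimetric PM2.5 (μg/m³), the
co-located continuous-monitor weekly mean, and filter light-absorbance for
black carbon (10⁻⁵ m⁻¹), plus sampler runtime and flow metadata.  Samples
are retained when the sampler ran for at least 75 % of the 7-day window and
held its flow within ±10 % of the intended 1 l/min; failed gravimetric
samples are replaced by correction-factor-scaled continuous means; one
absorbance unit is taken as 1.67 μg/m³ elemental carbon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_city import SeasonCalendar, DEFAULT_CALENDAR

#: μg/m³ elemental carbon per absorbance unit (1e-5 per metre).
EC_PER_ABSORBANCE_UNIT = 1.67


class DataError(ValueError):
    """Physically impossible measurement metadata (negative runtime/flow/absorbance)."""


@dataclass(frozen=True)
class QCConfig:
    """Inclusion rules for weekly samples; both bounds are closed."""

    min_runtime_fraction: float = 0.75
    flow_tolerance_fraction: float = 0.10
    intended_flow: float = 1.0  # litres per minute

    def __post_init__(self) -> None:
        if not (0.0 < self.min_runtime_fraction <= 1.0):
            raise ValueError("min_runtime_fraction must be in (0, 1]")
        if not (0.0 < self.flow_tolerance_fraction <= 1.0):
            raise ValueError("flow_tolerance_fraction must be in (0, 1]")
        if self.intended_flow <= 0:
            raise ValueError("intended_flow must be positive")


def qc_filter(table: pd.DataFrame, qc: QCConfig | None = None) -> pd.DataFrame:
    """Flag (never delete) rows by the runtime and flow inclusion rules.

    Adds/overwrites a boolean ``qc_pass`` column:
    ``runtime_fraction >= min`` AND ``|mean_flow - intended| <= tol * intended``,
    both bounds closed, so a sampler at exactly 75 % runtime passes.
    """
    qc = qc or QCConfig()
    for col in ("runtime_fraction", "mean_flow"):
        if col not in table.columns:
            raise KeyError(f"table lacks required column {col!r}")
        if (table[col].dropna() < 0).any():
            raise DataError(f"negative values in {col!r}")
    out = table.copy()
    runtime_ok = out["runtime_fraction"] >= qc.min_runtime_fraction
    # closed bound with a tiny relative slack so a deviation of exactly the
    # tolerance (e.g. |1.1 - 1.0| in binary floating point) still passes
    tol = qc.flow_tolerance_fraction * qc.intended_flow
    flow_ok = (out["mean_flow"] - qc.intended_flow).abs() <= tol * (1 + 1e-9)
    out["qc_pass"] = (runtime_ok & flow_ok).astype(bool)
    return out


def colocated_correction_factor(gravimetric: float, continuous_mean: float) -> float:
    """CF scaling the continuous weekly mean onto the gravimetric concentration.

    Defined so that CF × continuous mean equals the gravimetric value for the
    same site and 7-day window.
    """
    if gravimetric <= 0 or continuous_mean < 0:
        raise DataError("gravimetric must be > 0 and continuous mean >= 0")
    if continuous_mean == 0:
        raise ZeroDivisionError("continuous mean is zero; correction factor undefined")
    return gravimetric / continuous_mean


def estimate_correction_factors(
    table: pd.DataFrame, mode: str = "pooled"
) -> float | pd.Series:
    """Estimate the CF from co-located pairs that passed QC.

    ``pooled`` returns one campaign-wide CF (sum of gravimetric over sum of
    continuous, the measurement-weighted mean of pair-level CFs); ``per_site``
    returns a per-site Series with the pooled value as fallback.
    """
    if "qc_pass" not in table.columns:
        raise KeyError("run qc_filter before estimating correction factors")
    ok = table[
        table["qc_pass"]
        & table["pm25_gravimetric"].notna()
        & table["pm25_continuous_mean"].notna()
        & (table["pm25_continuous_mean"] > 0)
    ]
    if ok.empty:
        raise DataError("no QC-passing co-located pairs to estimate a CF from")
    pooled = float(ok["pm25_gravimetric"].sum() / ok["pm25_continuous_mean"].sum())
    if mode == "pooled":
        return pooled
    if mode == "per_site":
        grp = ok.groupby("site_id")
        cf = grp["pm25_gravimetric"].sum() / grp["pm25_continuous_mean"].sum()
        return cf.reindex(table["site_id"].unique()).fillna(pooled)
    raise ValueError("mode must be 'pooled' or 'per_site'")


def gap_fill(table: pd.DataFrame, cf: float | pd.Series) -> pd.DataFrame:
    """Build the analysis PM2.5 column, replacing failed gravimetric samples.

    Rows that passed QC with a gravimetric value keep it
    (``fill_source = 'gravimetric'``); rows without a usable gravimetric
    value but with a continuous weekly mean get ``CF × continuous``
    (``'corrected_continuous'``); rows with neither are ``'excluded'``.
    Negative continuous readings are treated as missing, not clipped to zero.
    """
    out = table.copy()
    if "qc_pass" not in out.columns:
        raise KeyError("run qc_filter before gap_fill")
    cont = out["pm25_continuous_mean"].where(out["pm25_continuous_mean"] >= 0)
    if isinstance(cf, pd.Series):
        cf_vals = out["site_id"].map(cf).to_numpy(dtype=float)
    else:
        cf_vals = np.full(len(out), float(cf))
    grav_ok = out["qc_pass"] & out["pm25_gravimetric"].notna()
    cont_ok = cont.notna()

    pm25 = np.where(grav_ok, out["pm25_gravimetric"], cf_vals * cont)
    source = np.where(
        grav_ok, "gravimetric", np.where(cont_ok, "corrected_continuous", "excluded")
    )
    pm25 = np.where(source == "excluded", np.nan, pm25)
    out["pm25"] = pm25
    out["fill_source"] = source
    return out


def absorbance_to_ec(a, factor: float = EC_PER_ABSORBANCE_UNIT):
    """Convert filter absorbance (10⁻⁵ m⁻¹) to elemental-carbon-equivalent μg/m³."""
    arr = np.asarray(a, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise DataError("absorbance must be non-negative")
    out = factor * arr
    return float(out) if np.isscalar(a) or arr.ndim == 0 else out


def label_season(month: int, calendar: SeasonCalendar = DEFAULT_CALENDAR) -> str:
    """'harmattan' iff month is November–February, else 'non_harmattan'."""
    return calendar.season_of_month(month)


def apply_qc_pipeline(
    table: pd.DataFrame,
    qc: QCConfig | None = None,
    cf_mode: str = "pooled",
) -> pd.DataFrame:
    """qc_filter → CF estimation → gap_fill, in one call."""
    flagged = qc_filter(table, qc)
    cf = estimate_correction_factors(flagged, mode=cf_mode)
    return gap_fill(flagged, cf)
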