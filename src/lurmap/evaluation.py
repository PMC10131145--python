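"""Model evaluation: 10-fold cross-validation with back-transformation,
error metrics, and Moran's I residual spatial autocorrelation.

Cross-validated predictions are compared with measurements on the original
concentration scale: log-PM2.5 predictions are exponentiated *before* any
metric is computed.  The reported metrics are pooled-out-of-fold Pearson r
and r², median absolute error (MAE) and mean error (ME = mean of predicted
minus measured).  Moran's I is computed on per-site mean residuals with
row-standardized inverse-distance (or k-nearest-neighbour) weights and a
permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lur import FittedLUR, fit_lmm


@dataclass
class CVResult:
    """Pooled out-of-fold prediction pairs (concentration scale) + metrics."""

    pairs: pd.DataFrame  # columns: fold, measured, predicted
    folds: np.ndarray
    r: float
    r2: float
    mae: float  # median absolute error
    me: float  # mean error (predicted - measured)
    seed: int
    k: int


@dataclass
class MoranResult:
    I: float
    expected: float  # -1/(n-1)
    p_value: float
    permutations: int
    weight_scheme: str
    seed: int


def make_folds(n: int, k: int = 10, seed: int = 0, groups=None) -> np.ndarray:
    """Random fold assignment (sizes differ by <= 1), deterministic per seed.

    With ``groups`` (e.g. site ids) whole groups are assigned to folds so
    that no group straddles the train/validation boundary.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    if groups is None:
        if n < k:
            raise ValueError(f"cannot make {k} folds from {n} records")
        order = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        for f, chunk in enumerate(np.array_split(order, k)):
            folds[chunk] = f
        return folds
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) < k:
        raise ValueError(f"cannot make {k} grouped folds from {len(uniq)} groups")
    order = rng.permutation(len(uniq))
    gfold = {}
    for f, chunk in enumerate(np.array_split(order, k)):
        for gi in chunk:
            gfold[uniq[gi]] = f
    return np.array([gfold[g] for g in groups], dtype=int)


def prediction_metrics(measured, predicted) -> dict[str, float]:
    """r, r², MAE (median absolute error), ME on concentration-scale pairs."""
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    err = predicted - measured
    r = float(np.corrcoef(measured, predicted)[0, 1]) if np.std(predicted) > 0 else 0.0
    return {
        "r": r,
        "r2": r * r,
        "mae": float(np.median(np.abs(err))),
        "me": float(err.mean()),
    }


def cross_validate(
    data: pd.DataFrame,
    terms: list[str],
    y_model,
    measured,
    site_ids,
    week_ids,
    k: int = 10,
    seed: int = 0,
    log_scale: bool = True,
    group_by_site: bool = False,
    **fit_kwargs,
) -> CVResult:
    """k-fold CV of a model with fixed terms (selection is not re-run).

    Per fold, coefficients are refit on the training 90 %; out-of-fold
    predictions use fixed effects only; with ``log_scale`` the predictions
    are exponentiated before comparison with ``measured``.
    """
    y_model = np.asarray(y_model, dtype=float)
    measured = np.asarray(measured, dtype=float)
    site_ids = np.asarray(site_ids)
    week_ids = np.asarray(week_ids)
    n = len(y_model)
    folds = make_folds(n, k, seed, groups=site_ids if group_by_site else None)
    predicted = np.full(n, np.nan)
    for f in range(k):
        val = folds == f
        train = ~val
        try:
            fit = fit_lmm(
                y_model[train],
                data.loc[train, terms] if terms else None,
                site_ids[train],
                week_ids[train],
                **fit_kwargs,
            )
        except np.linalg.LinAlgError as err:
            raise RuntimeError(f"fold {f} failed to fit: {err}") from err
        pred = fit.predict_fixed(data.loc[val, terms]) if terms else np.full(
            int(val.sum()), float(fit.params["intercept"])
        )
        predicted[val] = np.exp(pred) if log_scale else pred
    pairs = pd.DataFrame({"fold": folds, "measured": measured, "predicted": predicted})
    m = prediction_metrics(measured, predicted)
    return CVResult(pairs=pairs, folds=folds, seed=seed, k=k, **m)


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------


def _weight_matrix(coords: np.ndarray, scheme: str, knn: int) -> np.ndarray:
    n = len(coords)
    d = np.hypot(
        coords[:, 0][:, None] - coords[:, 0][None, :],
        coords[:, 1][:, None] - coords[:, 1][None, :],
    )
    if scheme == "inverse_distance":
        with np.errstate(divide="ignore"):
            w = 1.0 / d
        np.fill_diagonal(w, 0.0)
    elif scheme == "knn":
        w = np.zeros((n, n))
        for i in range(n):
            order = np.argsort(d[i])
            neigh = [j for j in order if j != i][:knn]
            w[i, neigh] = 1.0
    else:
        raise ValueError("scheme must be 'inverse_distance' or 'knn'")
    rs = w.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    return w / rs  # row-standardized


def morans_i(
    values,
    coords=None,
    scheme: str = "inverse_distance",
    knn: int = 8,
    permutations: int = 999,
    seed: int = 0,
    weights: np.ndarray | None = None,
) -> MoranResult:
    """Global Moran's I with a permutation p-value.

    ``values`` are one residual per site (average repeated residuals to the
    site level first).  ``weights`` overrides the built-in schemes with an
    explicit matrix (its diagonal must be zero); otherwise row-standardized
    inverse-distance weights over site coordinates are used.
    """
    z = np.asarray(values, dtype=float)
    n = len(z)
    if n < 3:
        raise ValueError("Moran's I needs >= 3 sites")
    if z.std() == 0:
        raise ValueError("constant residuals: Moran's I undefined")
    if weights is None:
        if coords is None:
            raise ValueError("either coords or an explicit weight matrix is required")
        w = _weight_matrix(np.asarray(coords, dtype=float), scheme, knn)
        scheme_name = scheme
    else:
        w = np.asarray(weights, dtype=float)
        if np.diag(w).any():
            raise ValueError("weight matrix diagonal must be zero")
        scheme_name = "custom"

    def stat(v: np.ndarray) -> float:
        zc = v - v.mean()
        return float(len(v) / w.sum() * (zc @ w @ zc) / (zc @ zc))

    I = stat(z)
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    if permutations > 0:
        null = np.array([stat(rng.permutation(z)) for _ in range(permutations)])
        extreme = int((np.abs(null - expected) >= abs(I - expected) - 1e-12).sum())
        p = (1 + extreme) / (permutations + 1)
    else:
        p = float("nan")
    return MoranResult(
        I=I, expected=expected, p_value=float(p), permutations=permutations,
        weight_scheme=scheme_name, seed=seed,
    )


def site_mean_residuals(
    fit: FittedLUR, data: pd.DataFrame, y, site_ids
) -> tuple[np.ndarray, np.ndarray]:
    """Average fixed-effects residuals to one value per site.

    Returns (site order, per-site mean residual); pair with site coordinates
    for :func:`morans_i`.
    """
    resid = np.asarray(y, dtype=float) - fit.predict_fixed(data[fit.term_names])
    s = pd.Series(resid).groupby(np.asarray(site_ids)).mean()
    return s.index.to_numpy(), s.to_numpy()
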