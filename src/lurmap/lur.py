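"""Linear mixed-effects LUR fitting and two-stage supervised variable selection.

Model
-----
For site *i* and week *t* the (possibly log-transformed) concentration is

    y_it = beta0 + x_it' beta + b_i + c_t + e_it,

with crossed (not nested) random intercepts b_i ~ N(0, sigma2_site) for
measurement site and c_t ~ N(0, sigma2_week) for week of the year, and
residual e_it ~ N(0, sigma2_eps).  PM2.5 enters as natural log; BC
absorbance on its natural scale.  Estimation is restricted maximum
likelihood: the two variance ratios are profiled out with a Woodbury
identity on the (site + week) indicator blocks, so each fit costs
O(q^3) with q = n_sites + n_weeks rather than O(n^3).

Selection
---------
Stage one ranks every candidate by |Pearson r| with the response, keeps the
best buffer radius per buffered variable, and drops candidates whose
correlation sign contradicts the a-priori sign registry.  Stage two is a
supervised forward pass in rank order: a candidate is accepted iff it adds
at least ``delta_adj_r2`` (default 0.01, absolute) to the fixed-effects
adjusted R², its coefficient is significant at ``alpha``, no VIF exceeds
``vif_max``, and the fitted sign matches expectation.  Accepted variables
are never removed.  A final re-inclusion pass retries every rejected
candidate once against the final model.  Month-of-year indicators travel as
one block candidate with a joint Wald test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .features import PredictorMatrix

_Z975 = stats.norm.ppf(0.975)


class RankError(np.linalg.LinAlgError):
    """Singular fixed-effects design; names the aliased columns."""


class ConvergenceError(RuntimeError):
    """REML optimisation failed to converge; carries the iteration log."""


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds of the supervised forward selection."""

    delta_adj_r2: float = 0.01  # absolute increase in adjusted R^2
    alpha: float = 0.05
    vif_max: float = 3.0
    sign_screen: bool = True
    reinclusion_pass: bool = True
    relative_delta: bool = False  # interpret delta_adj_r2 as a relative gain
    order: str = "contribution"  # "contribution" (largest gain) or "rank"

    def __post_init__(self) -> None:
        if self.delta_adj_r2 <= 0 and self.delta_adj_r2 != 0.0:
            raise ValueError("delta_adj_r2 must be >= 0")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        if self.vif_max <= 1.0:
            raise ValueError("vif_max must exceed 1")


# ---------------------------------------------------------------------------
# REML fitting of the crossed random-intercept model
# ---------------------------------------------------------------------------


def _design_checks(y: np.ndarray, X: np.ndarray, colnames: list[str]) -> None:
    n, p = X.shape
    if len(y) != n:
        raise ValueError("response and design have different lengths")
    Xi = np.column_stack([np.ones(n), X]) if p else np.ones((n, 1))
    rank = np.linalg.matrix_rank(Xi)
    if rank < Xi.shape[1]:
        # identify aliased columns through pivoted QR magnitude of R diagonal
        _, R = np.linalg.qr(Xi)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(Xi.shape) * np.finfo(float).eps
        bad = [colnames[i - 1] for i in range(1, Xi.shape[1]) if diag[i] <= tol]
        raise RankError(f"singular fixed-effects design; aliased columns: {bad or 'intercept'}")


@dataclass
class FittedLUR:
    """A fitted mixed-effects LUR: fixed coefficients with Wald inference,
    the three variance components, and the standardization contract."""

    response: str  # "log_pm25" or "bc"
    season: str | None
    term_names: list[str]
    params: pd.Series  # intercept + terms
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame  # columns lo, hi
    cov_params: pd.DataFrame
    sigma2_site: float
    sigma2_week: float
    sigma2_eps: float
    n_obs: int
    n_sites: int
    n_weeks: int
    converged: bool
    reml_criterion: float
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    def predict_fixed(self, X: pd.DataFrame) -> np.ndarray:
        """Fixed-effects-only linear predictor for new rows (model scale)."""
        missing = [t for t in self.term_names if t not in X.columns]
        if missing:
            raise KeyError(f"prediction input lacks columns {missing}")
        out = np.full(len(X), float(self.params["intercept"]))
        for t in self.term_names:
            out += float(self.params[t]) * X[t].to_numpy(dtype=float)
        return out

    def to_json(self) -> str:
        payload = {
            "response": self.response,
            "season": self.season,
            "term_names": self.term_names,
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "conf_int": {k: list(v) for k, v in self.conf_int.iterrows()},
            "sigma2_site": self.sigma2_site,
            "sigma2_week": self.sigma2_week,
            "sigma2_eps": self.sigma2_eps,
            "n_obs": self.n_obs,
            "n_sites": self.n_sites,
            "n_weeks": self.n_weeks,
            "converged": self.converged,
            "reml_criterion": self.reml_criterion,
            "standardization": {k: list(v) for k, v in self.standardization.items()},
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FittedLUR":
        d = json.loads(text)
        names = ["intercept"] + d["term_names"]
        ci = pd.DataFrame(
            [d["conf_int"][k] for k in names], index=names, columns=["lo", "hi"]
        )
        return cls(
            response=d["response"],
            season=d["season"],
            term_names=d["term_names"],
            params=pd.Series({k: d["params"][k] for k in names}),
            bse=pd.Series({k: d["bse"][k] for k in names}),
            pvalues=pd.Series({k: d["pvalues"][k] for k in names}),
            conf_int=ci,
            cov_params=pd.DataFrame(np.nan, index=names, columns=names),
            sigma2_site=d["sigma2_site"],
            sigma2_week=d["sigma2_week"],
            sigma2_eps=d["sigma2_eps"],
            n_obs=d["n_obs"],
            n_sites=d["n_sites"],
            n_weeks=d["n_weeks"],
            converged=d["converged"],
            reml_criterion=d["reml_criterion"],
            standardization={k: tuple(v) for k, v in d["standardization"].items()},
        )


def fit_lmm(
    y,
    X: pd.DataFrame | None,
    site_ids,
    week_ids,
    response: str = "log_pm25",
    season: str | None = None,
    include_week: bool = True,
    standardization: dict[str, tuple[float, float]] | None = None,
) -> FittedLUR:
    """REML fit of the crossed random-intercept LUR.

    ``y`` must already be on the modelling scale (natural log for PM2.5).
    ``X`` holds the fixed-effects columns without an intercept (``None`` or
    empty for an intercept-only model).
    """
    y = np.asarray(y, dtype=float)
    if X is None or (hasattr(X, "shape") and X.shape[1] == 0):
        X = pd.DataFrame(index=range(len(y)))
    colnames = list(X.columns)
    Xm = X.to_numpy(dtype=float) if len(colnames) else np.empty((len(y), 0))
    n = len(y)
    site_codes, site_levels = pd.factorize(np.asarray(site_ids), sort=True)
    week_codes, week_levels = pd.factorize(np.asarray(week_ids), sort=True)
    qs, qw = len(site_levels), len(week_levels)
    if qs < 2:
        raise ValueError("need >= 2 sites to identify a site random intercept")
    _design_checks(y, Xm, colnames)

    Xi = np.column_stack([np.ones(n), Xm])
    p = Xi.shape[1]
    if n <= p:
        raise ValueError("more fixed-effects parameters than observations")

    # degenerate: constant response
    if np.ptp(y) == 0.0:
        names = ["intercept"] + colnames
        params = pd.Series(0.0, index=names)
        params["intercept"] = y[0]
        zero = pd.Series(0.0, index=names)
        ci = pd.DataFrame({"lo": params, "hi": params})
        return FittedLUR(
            response=response, season=season, term_names=colnames,
            params=params, bse=zero, pvalues=pd.Series(1.0, index=names),
            conf_int=ci, cov_params=pd.DataFrame(0.0, index=names, columns=names),
            sigma2_site=0.0, sigma2_week=0.0, sigma2_eps=0.0,
            n_obs=n, n_sites=qs, n_weeks=qw, converged=True,
            reml_criterion=float("nan"),
            standardization=standardization or {},
        )

    nblocks = 2 if include_week else 1
    q = qs + (qw if include_week else 0)
    Z = np.zeros((n, q))
    Z[np.arange(n), site_codes] = 1.0
    if include_week:
        Z[np.arange(n), qs + week_codes] = 1.0
    ZtZ = Z.T @ Z
    ZtX = Z.T @ Xi
    Zty = Z.T @ y
    XtX = Xi.T @ Xi
    Xty = Xi.T @ y
    yty = float(y @ y)
    Iq = np.eye(q)

    def _solve(u):
        u = np.clip(u, -30.0, 10.0)
        gam = np.exp(u)
        d = np.repeat(gam, [qs, qw] if include_week else [qs])
        sq = np.sqrt(d)
        M = Iq + (sq[:, None] * ZtZ) * sq[None, :]
        cf = cho_factor(M, lower=True)
        logdet_v = 2.0 * float(np.log(np.diag(cf[0])).sum())
        B = sq[:, None] * ZtX
        b = sq * Zty
        MB = cho_solve(cf, B)
        Mb = cho_solve(cf, b)
        XtViX = XtX - B.T @ MB
        XtViy = Xty - B.T @ Mb
        ytViy = yty - float(b @ Mb)
        sign, logdet_xvx = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return None
        beta = np.linalg.solve(XtViX, XtViy)
        rss = ytViy - float(XtViy @ beta)
        rss = max(rss, 1e-12)
        sigma2 = rss / (n - p)
        crit = 0.5 * (logdet_v + (n - p) * math.log(sigma2) + logdet_xvx)
        return crit, beta, sigma2, XtViX, gam

    def objective(u):
        res = _solve(u)
        return np.inf if res is None else res[0]

    starts = [
        np.full(nblocks, math.log(0.5)),
        np.full(nblocks, math.log(0.05)),
        np.full(nblocks, -12.0),
        np.full(nblocks, math.log(2.0)),
    ]
    if nblocks == 2:
        starts += [np.array([-12.0, math.log(0.5)]), np.array([math.log(0.5), -12.0])]
    best_start = min(starts, key=objective)
    opt = optimize.minimize(
        objective,
        best_start,
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
    )
    res = _solve(opt.x)
    if res is None:
        raise ConvergenceError(f"REML solve failed at optimum; log: {opt}")
    crit, beta, sigma2, XtViX, gam = res
    converged = bool(opt.success)
    if not converged and not np.isfinite(crit):
        raise ConvergenceError(f"REML did not converge; iteration log: {opt}")

    # treat tiny boundary ratios as exact zeros
    gam = np.where(gam < 1e-8, 0.0, gam)
    sigma2_site = float(gam[0] * sigma2)
    sigma2_week = float(gam[1] * sigma2) if include_week else 0.0

    cov = sigma2 * np.linalg.inv(XtViX)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    names = ["intercept"] + colnames
    params = pd.Series(beta, index=names)
    bse = pd.Series(se, index=names)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=names)
    ci = pd.DataFrame(
        {"lo": beta - _Z975 * se, "hi": beta + _Z975 * se}, index=names
    )
    return FittedLUR(
        response=response,
        season=season,
        term_names=colnames,
        params=params,
        bse=bse,
        pvalues=pvals,
        conf_int=ci,
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        sigma2_site=sigma2_site,
        sigma2_week=sigma2_week,
        sigma2_eps=float(sigma2),
        n_obs=n,
        n_sites=qs,
        n_weeks=qw,
        converged=converged,
        reml_criterion=float(crit),
        standardization=standardization or {},
    )


# ---------------------------------------------------------------------------
# Fixed-effects R^2 and VIF
# ---------------------------------------------------------------------------


def fixed_effects_adj_r2(fit: FittedLUR, y, X: pd.DataFrame) -> tuple[float, float]:
    """(r², adjusted r²) of the fixed-effects-only prediction against ``y``.

    r² is the squared Pearson correlation between the observed response and
    the fixed-effects linear predictor; the adjustment uses
    p = number of non-intercept fixed terms.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    p = len(fit.term_names)
    if n <= p + 1:
        raise ValueError("adjusted R^2 undefined: n <= p + 1")
    yhat = fit.predict_fixed(X)
    if np.std(yhat) == 0.0 or np.std(y) == 0.0:
        r2 = 0.0 if np.std(yhat) == 0.0 and np.std(y) > 0 else 1.0
    else:
        r2 = float(np.corrcoef(y, yhat)[0, 1] ** 2)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return r2, float(adj)


def ols_adj_r2(y, X: pd.DataFrame | None) -> tuple[float, float]:
    """(R², adjusted R²) of the auxiliary fixed-effects-only OLS regression.

    This is the monotone selection metric: adding a column never decreases
    R², so the Δ-adjusted-R² acceptance gate is well defined even when the
    mixed model's GLS coefficients would not maximise the sample
    correlation.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X is None or X.shape[1] == 0:
        return 0.0, 0.0
    p = X.shape[1]
    if n <= p + 1:
        raise ValueError("adjusted R^2 undefined: n <= p + 1")
    Xi = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    coef, _, _, _ = np.linalg.lstsq(Xi, y, rcond=None)
    resid = y - Xi @ coef
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if sst == 0 else 1.0 - float((resid**2).sum()) / sst
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return float(r2), float(adj)


def model_vif(fit: FittedLUR) -> pd.Series:
    """Variance inflation factors from the fitted model's coefficient
    covariance (the quantity R's ``car::vif`` reports for a mixed model).

    VIF_j is the j-th diagonal of the inverse of the correlation matrix of
    the non-intercept coefficient covariance block; it reflects the
    collinearity the GLS fit actually experiences, with repeated fixed-site
    rows weighted through the random-intercept structure.
    """
    terms = fit.term_names
    if len(terms) <= 1:
        return pd.Series(1.0, index=terms)
    C = fit.cov_params.loc[terms, terms].to_numpy()
    d = np.sqrt(np.diag(C))
    if np.any(d <= 0):
        return pd.Series(np.inf, index=terms)
    R = C / np.outer(d, d)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        return pd.Series(np.inf, index=terms)
    return pd.Series(np.abs(np.diag(Rinv)), index=terms)


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column of a fixed design (no intercept).

    VIF_j = 1 / (1 − R²_j) from regressing column j on the other columns
    (with intercept).  A single column has VIF 1 by convention; perfect
    collinearity yields ``inf``.
    """
    cols = list(X.columns)
    if len(cols) == 1:
        return pd.Series([1.0], index=cols)
    Xm = X.to_numpy(dtype=float)
    out = {}
    n = Xm.shape[0]
    for j, c in enumerate(cols):
        target = Xm[:, j]
        others = np.column_stack([np.ones(n), np.delete(Xm, j, axis=1)])
        sst = float(((target - target.mean()) ** 2).sum())
        if sst == 0.0:
            out[c] = float("inf")
            continue
        coef, _, _, _ = np.linalg.lstsq(others, target, rcond=None)
        ssr = float(((target - others @ coef) ** 2).sum())
        r2 = 1.0 - ssr / sst
        out[c] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


# ---------------------------------------------------------------------------
# Stage one: correlation ranking, buffer choice, sign screen
# ---------------------------------------------------------------------------


@dataclass
class Candidate:
    """A selection candidate: one column, or one block of indicator columns."""

    name: str  # base variable name
    columns: list[str]
    expected_sign: str
    r: float  # signed Pearson r of the representative column


def rank_and_pick_buffers(
    matrix: PredictorMatrix, y, exclude: set[str] | None = None
) -> tuple[list[Candidate], list[Candidate]]:
    """Rank candidates by |Pearson r| with ``y``; keep one buffer per variable.

    Ties in |r| break toward the smaller buffer, then lexicographic name.
    Returns (candidates ordered by descending |r|, sign-screened rejects).
    Zero-variance columns are skipped.
    """
    y = np.asarray(y, dtype=float)
    exclude = exclude or set()
    df = matrix.data

    def corr(col: str) -> float:
        x = df[col].to_numpy(dtype=float)
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            return np.nan
        return float(np.corrcoef(x, y)[0, 1])

    by_base: dict[str, list[tuple[str, float]]] = {}
    for col in matrix.predictor_columns:
        meta = matrix.column_meta[col]
        if meta.base in exclude:
            continue
        by_base.setdefault(meta.base, []).append((col, corr(col)))

    candidates: list[Candidate] = []
    for base, cols in by_base.items():
        usable = [(c, r) for c, r in cols if np.isfinite(r)]
        if not usable:
            continue
        if base == "month":
            # indicator block; constant-in-subset indicators are dropped
            best = max(usable, key=lambda t: abs(t[1]))
            candidates.append(
                Candidate(base, [c for c, _ in usable], "unconstrained", best[1])
            )
            continue
        # max |r|; tie -> smaller buffer, then name
        def key(t):
            col, r = t
            buf = matrix.column_meta[col].buffer
            return (-abs(r), buf if buf is not None else 0.0, col)

        col, r = sorted(usable, key=key)[0]
        candidates.append(Candidate(base, [col], matrix.column_meta[col].expected_sign, r))

    candidates.sort(key=lambda c: (-abs(c.r), c.name))
    kept, sign_rejected = [], []
    for c in candidates:
        if c.expected_sign == "+" and c.r < 0 or c.expected_sign == "-" and c.r > 0:
            sign_rejected.append(c)
        else:
            kept.append(c)
    return kept, sign_rejected


# ---------------------------------------------------------------------------
# Stage two: supervised forward selection with re-inclusion
# ---------------------------------------------------------------------------


@dataclass
class SelectionStep:
    candidate: str
    columns: list[str]
    phase: str  # "rank_sign_screen", "forward", "reinclusion"
    adj_r2_before: float
    adj_r2_after: float | None
    p_value: float | None
    max_vif: float | None
    decision: str  # accepted / rejected_r2 / rejected_p / rejected_vif / rejected_sign
    cumulative_r2: float | None = None  # fixed-effects R^2 after acceptance
    expected_sign: str = "unconstrained"


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)
    accepted: list[Candidate] = field(default_factory=list)
    config: SelectionConfig = field(default_factory=SelectionConfig)

    @property
    def accepted_columns(self) -> list[str]:
        return [c for cand in self.accepted for c in cand.columns]

    def replay(self, data: pd.DataFrame, y, site_ids, week_ids, **fit_kwargs) -> FittedLUR:
        """Refit the accepted terms in order; reproduces the final model."""
        return fit_lmm(y, data[self.accepted_columns], site_ids, week_ids, **fit_kwargs)

    def to_records(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(s) for s in self.steps])


def _candidate_p(fit: FittedLUR, columns: list[str]) -> float:
    """Wald p for a single coefficient, or joint Wald chi² for a block."""
    if len(columns) == 1:
        return float(fit.pvalues[columns[0]])
    b = fit.params[columns].to_numpy()
    C = fit.cov_params.loc[columns, columns].to_numpy()
    try:
        w = float(b @ np.linalg.solve(C, b))
    except np.linalg.LinAlgError:
        return 1.0
    return float(stats.chi2.sf(w, df=len(columns)))


def _sign_ok(fit: FittedLUR, cand: Candidate) -> bool:
    if cand.expected_sign == "unconstrained":
        return True
    coef = float(fit.params[cand.columns[0]])
    return coef > 0 if cand.expected_sign == "+" else coef < 0


def _evaluate_candidate(
    cand: Candidate,
    state_fit: FittedLUR | None,
    adj_before: float,
    accepted_cols: list[str],
    data: pd.DataFrame,
    y,
    site_ids,
    week_ids,
    cfg: SelectionConfig,
    phase: str,
    fit_kwargs: dict,
):
    cols = accepted_cols + cand.columns
    try:
        trial = fit_lmm(y, data[cols], site_ids, week_ids, **fit_kwargs)
    except (RankError, np.linalg.LinAlgError):
        step = SelectionStep(cand.name, cand.columns, phase, adj_before, None,
                             None, float("inf"), "rejected_vif")
        return None, step
    r2_after, adj_after = ols_adj_r2(y, data[cols])
    max_vif = float(model_vif(trial).max())
    p_val = _candidate_p(trial, cand.columns)
    gain = adj_after - adj_before
    if cfg.relative_delta and adj_before > 0:
        gain = gain / adj_before
    decision = "accepted"
    if max_vif > cfg.vif_max:
        decision = "rejected_vif"
    elif cfg.sign_screen and not _sign_ok(trial, cand):
        decision = "rejected_sign"
    elif p_val >= cfg.alpha:
        decision = "rejected_p"
    elif gain < cfg.delta_adj_r2:
        decision = "rejected_r2"
    step = SelectionStep(
        cand.name, cand.columns, phase, adj_before, adj_after, p_val, max_vif,
        decision, cumulative_r2=r2_after if decision == "accepted" else None,
        expected_sign=cand.expected_sign,
    )
    return (trial if decision == "accepted" else None), step


def forward_select(
    candidates: list[Candidate],
    data: pd.DataFrame,
    y,
    site_ids,
    week_ids,
    cfg: SelectionConfig | None = None,
    sign_rejected: list[Candidate] | None = None,
    **fit_kwargs,
) -> tuple[FittedLUR, SelectionTrace]:
    """Supervised forward pass in rank order over stage-one candidates.

    Accepted variables are never removed; the pass ends when every candidate
    has been tried.  With an empty candidate list the result is the
    intercept-only model and an empty trace.
    """
    cfg = cfg or SelectionConfig()
    trace = SelectionTrace(config=cfg)
    for c in sign_rejected or []:
        trace.steps.append(
            SelectionStep(c.name, c.columns, "rank_sign_screen", 0.0, None, None,
                          None, "rejected_sign", expected_sign=c.expected_sign)
        )
    y = np.asarray(y, dtype=float)
    fit = fit_lmm(y, None, site_ids, week_ids, **fit_kwargs)
    adj = 0.0

    if cfg.order == "rank":
        for cand in candidates:
            accepted_fit, step = _evaluate_candidate(
                cand, fit, adj, trace.accepted_columns, data, y, site_ids, week_ids,
                cfg, "forward", fit_kwargs,
            )
            trace.steps.append(step)
            if accepted_fit is not None:
                fit = accepted_fit
                trace.accepted.append(cand)
                adj = step.adj_r2_after
        return fit, trace
    if cfg.order != "contribution":
        raise ValueError("order must be 'contribution' or 'rank'")

    # greedy by added contribution: each round evaluates every remaining
    # candidate (in rank order) and accepts the qualifying one with the
    # largest adjusted-R^2 gain; the first round therefore starts from the
    # highest-|r| candidate, whose gain is its squared correlation
    remaining = list(candidates)
    while remaining:
        evaluations = []
        for cand in remaining:
            accepted_fit, step = _evaluate_candidate(
                cand, fit, adj, trace.accepted_columns, data, y, site_ids,
                week_ids, cfg, "forward", fit_kwargs,
            )
            evaluations.append((cand, accepted_fit, step))
        qualifying = [e for e in evaluations if e[1] is not None]
        if not qualifying:
            trace.steps.extend(s for _, _, s in evaluations)
            break
        best = max(
            qualifying,
            key=lambda e: (e[2].adj_r2_after, abs(e[0].r) if np.isfinite(e[0].r) else 0.0),
        )
        # record only the winner this round; losers are re-evaluated (and
        # recorded) against the grown model in later rounds
        trace.steps.append(best[2])
        fit = best[1]
        trace.accepted.append(best[0])
        adj = best[2].adj_r2_after
        remaining = [c for c in remaining if c.name != best[0].name]
    return fit, trace


def reinclusion_pass(
    fit: FittedLUR,
    trace: SelectionTrace,
    data: pd.DataFrame,
    y,
    site_ids,
    week_ids,
    cfg: SelectionConfig | None = None,
    **fit_kwargs,
) -> tuple[FittedLUR, SelectionTrace]:
    """Retry every rejected candidate once against the final model.

    Candidates are retried in their original order; the trace grows by
    exactly the number of rejected candidates.
    """
    cfg = cfg or trace.config
    rejected: list[tuple[str, list[str], str]] = []
    accepted_names = {c.name for c in trace.accepted}
    seen = set()
    for s in trace.steps:
        if s.decision != "accepted" and s.candidate not in accepted_names and s.candidate not in seen:
            rejected.append((s.candidate, s.columns, s.expected_sign))
            seen.add(s.candidate)
    y = np.asarray(y, dtype=float)
    _, adj = ols_adj_r2(y, data[trace.accepted_columns] if trace.accepted else None)
    for name, cols, sign in rejected:
        cand = Candidate(name, cols, sign, float("nan"))
        accepted_fit, step = _evaluate_candidate(
            cand, fit, adj, trace.accepted_columns, data, y, site_ids, week_ids,
            cfg, "reinclusion", fit_kwargs,
        )
        trace.steps.append(step)
        if accepted_fit is not None:
            fit = accepted_fit
            trace.accepted.append(cand)
            adj = step.adj_r2_after
    return fit, trace


def select_lur(
    matrix: PredictorMatrix,
    y,
    site_ids,
    week_ids,
    cfg: SelectionConfig | None = None,
    exclude: set[str] | None = None,
    **fit_kwargs,
) -> tuple[FittedLUR, SelectionTrace]:
    """Full two-stage selection: rank + buffer pick + sign screen, forward
    pass, then the re-inclusion pass (if enabled)."""
    cfg = cfg or SelectionConfig()
    candidates, sign_rejected = rank_and_pick_buffers(matrix, y, exclude=exclude)
    if not cfg.sign_screen:
        candidates = sorted(candidates + sign_rejected, key=lambda c: (-abs(c.r), c.name))
        sign_rejected = []
    fit, trace = forward_select(
        candidates, matrix.data, y, site_ids, week_ids, cfg,
        sign_rejected=sign_rejected, **fit_kwargs,
    )
    if cfg.reinclusion_pass:
        fit, trace = reinclusion_pass(
            fit, trace, matrix.data, y, site_ids, week_ids, cfg, **fit_kwargs
        )
    fit.standardization = dict(matrix.standardization)
    return fit, trace
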