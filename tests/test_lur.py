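"""Mixed-model estimation against closed-form and library oracles, VIF,
and the two-stage supervised selection algorithm."""

import numpy as np
import pandas as pd
import pytest

import lurmap.features as ft
from lurmap import lur


def _crossed_data(seed=5, n_site=12, n_week=10, beta=(1.0, 0.8),
                  s_site=0.5, s_week=0.3, s_eps=0.4):
    rng = np.random.default_rng(seed)
    rows = [(s, w) for s in range(n_site) for w in range(n_week)]
    df = pd.DataFrame(rows, columns=["site", "week"])
    df["x"] = rng.normal(size=len(df))
    b_s = rng.normal(0, s_site, n_site)
    b_w = rng.normal(0, s_week, n_week)
    df["y"] = (beta[0] + beta[1] * df.x + b_s[df.site] + b_w[df.week]
               + rng.normal(0, s_eps, len(df)))
    return df


class TestFitLMM:
    def test_noise_free_matches_ols_exactly(self):
        rng = np.random.default_rng(0)
        n = 60
        x = rng.normal(size=n)
        y = 1.5 + 2.0 * x  # no noise at all
        fit = lur.fit_lmm(y, pd.DataFrame({"x": x}),
                          rng.integers(0, 6, n), rng.integers(0, 8, n))
        assert fit.params["intercept"] == pytest.approx(1.5, rel=1e-6)
        assert fit.params["x"] == pytest.approx(2.0, rel=1e-6)

    def test_zero_variance_simulation_matches_ols(self):
        # generated with sigma2_site = sigma2_week = 0: REML pushes both
        # ratios to the boundary and the GLS fit collapses to OLS
        rng = np.random.default_rng(3)
        n = 300
        x = rng.normal(size=n)
        y = 0.5 + 1.2 * x + rng.normal(0, 0.3, n)
        sites = rng.integers(0, 20, n)
        weeks = rng.integers(0, 15, n)
        fit = lur.fit_lmm(y, pd.DataFrame({"x": x}), sites, weeks)
        Xi = np.column_stack([np.ones(n), x])
        ols = np.linalg.lstsq(Xi, y, rcond=None)[0]
        assert fit.sigma2_site == pytest.approx(0.0, abs=1e-6)
        assert fit.sigma2_week == pytest.approx(0.0, abs=1e-6)
        assert fit.params["intercept"] == pytest.approx(ols[0], rel=1e-6)
        assert fit.params["x"] == pytest.approx(ols[1], rel=1e-6)

    def test_balanced_one_way_matches_anova_estimator(self):
        # oracle: closed-form method-of-moments for the balanced one-way layout
        rng = np.random.default_rng(3)
        k, m = 10, 8
        b = rng.normal(0, 0.7, k)
        y = np.concatenate([b[i] + rng.normal(0, 0.4, m) for i in range(k)])
        sites = np.repeat(np.arange(k), m)
        fit = lur.fit_lmm(y, None, sites, np.zeros(len(y)), include_week=False)
        group_means = y.reshape(k, m).mean(axis=1)
        msb = m * ((group_means - y.mean()) ** 2).sum() / (k - 1)
        msw = ((y.reshape(k, m) - group_means[:, None]) ** 2).sum() / (k * (m - 1))
        assert fit.sigma2_eps == pytest.approx(msw, rel=1e-3)
        assert fit.sigma2_site == pytest.approx((msb - msw) / m, rel=1e-3)

    def test_matches_statsmodels_crossed_reml(self):
        sm = pytest.importorskip("statsmodels.formula.api")
        df = _crossed_data()
        fit = lur.fit_lmm(df.y, df[["x"]], df.site, df.week)
        md = sm.mixedlm("y ~ x", df, groups=np.ones(len(df)),
                        vc_formula={"site": "0 + C(site)", "week": "0 + C(week)"})
        ref = md.fit(reml=True)
        assert fit.params["x"] == pytest.approx(ref.fe_params["x"], abs=1e-5)
        assert fit.params["intercept"] == pytest.approx(ref.fe_params["Intercept"], abs=1e-5)
        assert fit.sigma2_site == pytest.approx(ref.vcomp[0], rel=1e-3)
        assert fit.sigma2_week == pytest.approx(ref.vcomp[1], rel=1e-3)
        assert fit.sigma2_eps == pytest.approx(ref.scale, rel=1e-3)
        assert fit.bse["x"] == pytest.approx(ref.bse_fe["x"], rel=1e-2)

    def test_constant_response(self):
        y = np.full(40, 3.5)
        fit = lur.fit_lmm(y, pd.DataFrame({"x": np.arange(40.0)}),
                          np.arange(40) % 5, np.arange(40) % 7)
        assert fit.sigma2_eps == 0.0
        assert fit.params["x"] == 0.0
        assert fit.params["intercept"] == 3.5

    def test_singular_design_names_column(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(lur.RankError, match="b"):
            lur.fit_lmm(x + 1, X, np.arange(50) % 5, np.arange(50) % 7)

    def test_json_round_trip(self):
        df = _crossed_data(seed=8)
        fit = lur.fit_lmm(df.y, df[["x"]], df.site, df.week,
                          standardization={"x": (0.0, 1.0)})
        back = lur.FittedLUR.from_json(fit.to_json())
        pd.testing.assert_series_equal(back.params, fit.params)
        assert back.sigma2_site == fit.sigma2_site
        assert back.standardization == fit.standardization


class TestRSquared:
    def test_closed_form_adjustment(self):
        # n=11, p=1, r2=0.5 exactly -> adj = 1 - 0.5*10/9 = 0.4444
        n = 11
        x = np.arange(n, dtype=float)
        xc = x - x.mean()
        e = np.zeros(n)
        e[0], e[1] = 1.0, -1.0
        e -= e.mean()
        e -= (e @ xc) / (xc @ xc) * xc  # orthogonal to x and intercept
        y = xc + e * np.linalg.norm(xc) / np.linalg.norm(e)
        r2, adj = lur.ols_adj_r2(y, pd.DataFrame({"x": x}))
        assert r2 == pytest.approx(0.5, abs=1e-12)
        assert adj == pytest.approx(1 - 0.5 * 10 / 9, abs=1e-12)

    def test_exact_fit_gives_one(self):
        x = np.arange(20, dtype=float)
        fit = lur.fit_lmm(2 * x + 1, pd.DataFrame({"x": x}),
                          np.arange(20) % 4, np.arange(20) % 5)
        r2, adj = lur.fixed_effects_adj_r2(fit, 2 * x + 1, pd.DataFrame({"x": x}))
        assert r2 == pytest.approx(1.0)
        assert adj == pytest.approx(1.0)

    def test_equals_direct_pearson_oracle(self):
        df = _crossed_data(seed=21)
        fit = lur.fit_lmm(df.y, df[["x"]], df.site, df.week)
        r2, _ = lur.fixed_effects_adj_r2(fit, df.y, df[["x"]])
        yhat = fit.params["intercept"] + fit.params["x"] * df.x
        sy, syh = df.y - df.y.mean(), yhat - yhat.mean()
        direct = float((sy @ syh) ** 2 / ((sy @ sy) * (syh @ syh)))
        assert r2 == pytest.approx(direct, rel=1e-10)


class TestVIF:
    def test_orthogonal_columns(self):
        n = 40
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        out = lur.vif(pd.DataFrame({"a": x1, "b": x2}))
        assert out.tolist() == pytest.approx([1.0, 1.0])

    def test_correlation_08_closed_form(self):
        # oracle: 1/(1-0.64) = 2.778 from the auxiliary regression
        rng = np.random.default_rng(2)
        n = 500
        z1 = rng.normal(size=n)
        z2 = rng.normal(size=n)
        for z in (z1, z2):
            z -= z.mean()
        z2 -= (z2 @ z1) / (z1 @ z1) * z1
        z1 /= np.linalg.norm(z1)
        z2 /= np.linalg.norm(z2)
        x2 = 0.8 * z1 + np.sqrt(1 - 0.64) * z2
        out = lur.vif(pd.DataFrame({"a": z1, "b": x2}))
        assert out["a"] == pytest.approx(1 / (1 - 0.64), rel=1e-9)
        assert out["b"] == pytest.approx(2.778, abs=1e-3)

    def test_duplicate_column_infinite(self):
        x = np.arange(30.0)
        out = lur.vif(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(out).all()

    def test_single_column_convention(self):
        assert lur.vif(pd.DataFrame({"a": np.arange(5.0)})).tolist() == [1.0]


def _toy_matrix(cols, meta_signs=None, n=None):
    n = n or len(next(iter(cols.values())))
    df = pd.DataFrame({"site_id": [f"s{i}" for i in range(n)],
                       "week_index": np.arange(n) % 13 + 1, **cols})
    meta = {}
    spatial = []
    for c in cols:
        base, _, buf = c.rpartition("_")
        if buf.isdigit() and base:
            meta[c] = ft.ColumnMeta(base, float(buf), (meta_signs or {}).get(base, "unconstrained"), True, "spatial")
        else:
            meta[c] = ft.ColumnMeta(c, None, (meta_signs or {}).get(c, "unconstrained"), True, "spatial")
        spatial.append(c)
    return ft.PredictorMatrix(df, spatial, [], meta)


class TestRankAndPick:
    def test_picks_buffer_with_highest_abs_r(self):
        rng = np.random.default_rng(0)
        n = 200
        sig = rng.normal(size=n)
        cols = {
            "v_50": 0.3 * sig + np.sqrt(1 - 0.09) * rng.normal(size=n),
            "v_100": 0.5 * sig + np.sqrt(1 - 0.25) * rng.normal(size=n),
            "v_200": 0.4 * sig + np.sqrt(1 - 0.16) * rng.normal(size=n),
        }
        m = _toy_matrix(cols)
        cands, _ = lur.rank_and_pick_buffers(m, sig)
        assert cands[0].columns == ["v_100"]
        # oracle: exhaustive correlation table
        rs = {c: abs(np.corrcoef(m.data[c], sig)[0, 1]) for c in cols}
        assert max(rs, key=rs.get) == "v_100"

    def test_tie_breaks_toward_smaller_buffer(self):
        x = np.arange(50, dtype=float)
        m = _toy_matrix({"v_50": x.copy(), "v_500": x.copy()})
        cands, _ = lur.rank_and_pick_buffers(m, x)
        assert cands[0].columns == ["v_50"]

    def test_sign_screen_rejects_contradiction(self):
        x = np.arange(60, dtype=float)
        m = _toy_matrix({"ndvi_100": x.copy()}, meta_signs={"ndvi": "-"})
        kept, rejected = lur.rank_and_pick_buffers(m, x)  # positive r vs "-"
        assert kept == []
        assert rejected[0].name == "ndvi"

    def test_zero_variance_candidate_skipped(self):
        x = np.arange(30, dtype=float)
        m = _toy_matrix({"flat_50": np.ones(30), "v_50": x.copy()})
        cands, _ = lur.rank_and_pick_buffers(m, x)
        assert [c.name for c in cands] == ["v"]


def _selection_data(seed=0, n=600, beta2=0.0):
    rng = np.random.default_rng(seed)
    sites = np.array([f"s{i}" for i in range(120)]).repeat(5)[:n]
    weeks = np.arange(n) % 26 + 1
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    y = 1.0 + 0.8 * x1 + beta2 * x2 + rng.normal(0, 0.6, n)
    data = pd.DataFrame({"x1": x1, "x2": x2})
    return data, y, sites, weeks


class TestForwardSelect:
    def test_single_weak_candidate_gives_intercept_only(self):
        data, y, sites, weeks = _selection_data(seed=4)
        cand = [lur.Candidate("x2", ["x2"], "unconstrained",
                              float(np.corrcoef(data.x2, y)[0, 1]))]
        fit, trace = lur.forward_select(cand, data, y, sites, weeks)
        assert fit.term_names == []
        assert len(trace.steps) == 1
        assert trace.steps[0].decision in ("rejected_p", "rejected_r2")

    def test_signal_vs_noise_matches_subset_oracle(self):
        data, y, sites, weeks = _selection_data(seed=7)
        cands, _ = lur.rank_and_pick_buffers(
            _toy_matrix({"x1_50": data.x1, "x2_50": data.x2}, n=len(y)), y)
        fit, trace = lur.forward_select(cands, data.rename(
            columns={"x1": "x1_50", "x2": "x2_50"}), y, sites, weeks)
        assert fit.term_names == ["x1_50"]
        # oracle: evaluate all four subsets under the same accept criteria
        cfg = lur.SelectionConfig()
        best = None
        for subset in ([], ["x1_50"], ["x2_50"], ["x1_50", "x2_50"]):
            ok = True
            prev = 0.0
            cols = []
            for term in subset:
                trial = lur.fit_lmm(y, data.rename(columns={"x1": "x1_50", "x2": "x2_50"})[cols + [term]], sites, weeks)
                _, adj = lur.ols_adj_r2(y, data.rename(columns={"x1": "x1_50", "x2": "x2_50"})[cols + [term]])
                if (adj - prev < cfg.delta_adj_r2
                        or trial.pvalues[term] >= cfg.alpha):
                    ok = False
                    break
                cols.append(term)
                prev = adj
            if ok and (best is None or len(subset) > len(best)):
                best = subset
        assert best == ["x1_50"]

    def test_collinear_candidate_rejected_by_vif(self):
        rng = np.random.default_rng(3)
        n = 400
        sites = np.array([f"s{i}" for i in range(80)]).repeat(5)
        weeks = np.arange(n) % 20 + 1
        x1 = rng.normal(size=n)
        x2 = 0.995 * x1 + np.sqrt(1 - 0.995**2) * rng.normal(size=n)
        y = 1.0 + 0.9 * x1 + rng.normal(0, 0.4, n)
        data = pd.DataFrame({"x1": x1, "x2": x2})
        cands = [lur.Candidate("x1", ["x1"], "unconstrained", 0.9),
                 lur.Candidate("x2", ["x2"], "unconstrained", 0.85)]
        fit, trace = lur.forward_select(cands, data, y, sites, weeks)
        assert fit.term_names == ["x1"]
        steps = {s.candidate: s.decision for s in trace.steps if s.phase == "forward"}
        assert steps["x2"] == "rejected_vif"

    def test_rank_order_mode_accepts_in_rank_order(self):
        rng = np.random.default_rng(11)
        n = 500
        sites = np.array([f"s{i}" for i in range(100)]).repeat(5)
        weeks = np.arange(n) % 25 + 1
        x1, x2, x3 = rng.normal(size=(3, n))
        y = 0.9 * x1 + 0.6 * x2 + 0.4 * x3 + rng.normal(0, 0.5, n)
        data = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        cfg = lur.SelectionConfig(delta_adj_r2=1e-9, alpha=1.0,
                                  vif_max=np.inf, sign_screen=False,
                                  reinclusion_pass=False, order="rank")
        cands = [lur.Candidate(c, [c], "unconstrained",
                               float(np.corrcoef(data[c], y)[0, 1]))
                 for c in ["x1", "x2", "x3"]]
        fit, trace = lur.forward_select(cands, data, y, sites, weeks, cfg)
        assert [c.name for c in trace.accepted] == ["x1", "x2", "x3"]

    def test_contribution_mode_accepts_largest_gain_first(self):
        rng = np.random.default_rng(13)
        n = 500
        sites = np.array([f"s{i}" for i in range(100)]).repeat(5)
        weeks = np.arange(n) % 25 + 1
        x1, x2 = rng.normal(size=(2, n))
        y = 0.3 * x1 + 0.9 * x2 + rng.normal(0, 0.5, n)
        data = pd.DataFrame({"x1": x1, "x2": x2})
        cands = [lur.Candidate("x1", ["x1"], "unconstrained", 0.99),  # listed first
                 lur.Candidate("x2", ["x2"], "unconstrained", 0.5)]
        fit, trace = lur.forward_select(cands, data, y, sites, weeks)
        assert trace.accepted[0].name == "x2"  # larger added contribution

    def test_cumulative_r2_non_decreasing(self, small_campaign):
        import lurmap.pipeline as pl
        fit, trace = pl.fit_seasonal_lur(small_campaign, "pm25",
                                         "non_harmattan", spatial_only=True)
        cum = [s.cumulative_r2 for s in trace.steps if s.decision == "accepted"]
        assert all(a <= b + 1e-9 for a, b in zip(cum, cum[1:]))

    def test_trace_replay_reproduces_model(self, small_campaign):
        import lurmap.pipeline as pl
        d = pl.seasonal_data(small_campaign, "pm25", "non_harmattan")
        sub = small_campaign.matrix.copy()
        sub.data = d["data"]
        excl = {e.name for e in small_campaign.registry.temporal()}
        fit, trace = lur.select_lur(sub, d["y_model"], d["site_ids"],
                                    d["week_ids"], exclude=excl)
        replay = trace.replay(d["data"], d["y_model"], d["site_ids"], d["week_ids"])
        assert replay.term_names == fit.term_names
        assert np.array_equal(replay.params.to_numpy(), fit.params.to_numpy())


class TestReinclusion:
    def test_no_qualifier_leaves_model_unchanged(self):
        data, y, sites, weeks = _selection_data(seed=9)
        data = data.rename(columns={"x1": "a", "x2": "b"})
        cands = [lur.Candidate("a", ["a"], "unconstrained", 0.8),
                 lur.Candidate("b", ["b"], "unconstrained", 0.01)]
        fit, trace = lur.forward_select(cands, data, y, sites, weeks)
        n_before = len(trace.steps)
        rejected = {s.candidate for s in trace.steps} - {c.name for c in trace.accepted}
        fit2, trace2 = lur.reinclusion_pass(fit, trace, data, y, sites, weeks)
        assert fit2.term_names == fit.term_names
        assert len(trace2.steps) == n_before + len(rejected)

    def test_suppressed_candidate_recovered(self):
        # b is useless alone but strong given a: rejected in a rank-order
        # forward pass that tries it first, then re-included
        rng = np.random.default_rng(17)
        n = 600
        sites = np.array([f"s{i}" for i in range(120)]).repeat(5)
        weeks = np.arange(n) % 30 + 1
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        y = 1.0 + 1.0 * a + 1.0 * b - 0.0 + rng.normal(0, 0.3, n)
        # make b marginally uncorrelated with y by construction
        b_only = b - (b @ (y - y.mean())) / ((y - y.mean()) @ (y - y.mean())) * (y - y.mean())
        y2 = 1.0 + 1.0 * a + 1.0 * b_only + rng.normal(0, 0.3, n)
        data = pd.DataFrame({"a": a, "b": b_only})
        cfg = lur.SelectionConfig(order="rank")
        cands = [lur.Candidate("b", ["b"], "unconstrained", 0.02),
                 lur.Candidate("a", ["a"], "unconstrained", 0.7)]
        fit, trace = lur.forward_select(cands, data, y2, sites, weeks, cfg)
        fit2, trace2 = lur.reinclusion_pass(fit, trace, data, y2, sites, weeks, cfg)
        assert set(fit2.term_names) == {"a", "b"}
        last = trace2.steps[-1]
        assert last.phase == "reinclusion" and last.decision == "accepted"
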