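"""Inference layer: screening, mixed models, SEM, mediation, comparisons."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from trophostab import BenchSpec, generate_benchmark
from trophostab.stats import (
    default_dag,
    fit_glmm,
    fit_piecewise_sem,
    group_compare,
    mediation,
    quantile_partial_correlation,
    rf_importance,
    vif_screen,
)


class TestVif:
    def test_orthogonal_predictors(self):
        x1 = np.tile([1.0, -1.0], 50)
        x2 = np.repeat([1.0, -1.0], 50)
        df = pd.DataFrame({"x1": x1, "x2": x2})
        out = vif_screen(df, ["x1", "x2"])
        np.testing.assert_allclose(out["vif"], 1.0, atol=1e-10)
        assert not out["flagged"].any()

    def test_duplicated_predictor_is_infinite(self):
        x = np.arange(30, dtype=float)
        df = pd.DataFrame({"x1": x, "x2": x})
        out = vif_screen(df, ["x1", "x2"])
        assert np.isinf(out["vif"]).all()
        assert out["flagged"].all()

    def test_known_correlation_closed_form(self):
        # deterministic design with corr(x1, x2) = 0.8 exactly
        x1 = np.tile([1.0, -1.0], 50)
        z = np.repeat([1.0, -1.0], 50)
        x2 = 0.8 * x1 + 0.6 * z
        df = pd.DataFrame({"x1": x1, "x2": x2})
        out = vif_screen(df, ["x1", "x2"])
        np.testing.assert_allclose(out["vif"], 1.0 / (1.0 - 0.64), rtol=1e-9)


class TestGlmm:
    def test_coefficient_recovery(self):
        bench = BenchSpec(effects={"x1": 0.5, "x2": -0.3, "x3": 0.0},
                          random_sd=0.3, n=500)
        res = fit_glmm(generate_benchmark(bench, seed=2), "y",
                       ["x1", "x2", "x3"])
        assert 0.4 <= res.table.loc["x1", "beta"] <= 0.6
        assert -0.4 <= res.table.loc["x2", "beta"] <= -0.2
        assert abs(res.table.loc["x3", "beta"]) < 0.1

    def test_null_response_has_small_coefficients(self):
        bench = BenchSpec(effects={"x1": 0.0, "x2": 0.0}, random_sd=0.0, n=500)
        res = fit_glmm(generate_benchmark(bench, seed=3), "y", ["x1", "x2"])
        assert (res.table["beta"].abs() < 0.1).all()

    def test_no_group_effect_collapses_r2(self):
        bench = BenchSpec(effects={"x1": 0.5}, random_sd=0.0, n=500)
        res = fit_glmm(generate_benchmark(bench, seed=4), "y", ["x1"])
        assert res.r2c - res.r2m == pytest.approx(0.0, abs=0.02)


class TestRandomForest:
    @pytest.fixture(scope="class")
    def frame(self):
        bench = BenchSpec(effects={"x1": 0.7, "x2": 0.0}, random_sd=0.0, n=300)
        fr = generate_benchmark(bench, seed=5)
        fr["y_copy"] = fr["y"]
        return fr

    def test_duplicated_response_ranks_first(self, frame):
        out = rf_importance(frame, "y", ["x1", "x2", "y_copy"],
                            n_trees=200, seed=0)
        assert list(out["predictor"])[0] == "y_copy"

    def test_noise_ranks_last(self, frame):
        out = rf_importance(frame, "y", ["x1", "x2"], n_trees=200, seed=0)
        assert list(out["predictor"]) == ["x1", "x2"]

    def test_same_seed_same_ranking(self, frame):
        a = rf_importance(frame, "y", ["x1", "x2"], n_trees=100, seed=1)
        b = rf_importance(frame, "y", ["x1", "x2"], n_trees=100, seed=1)
        pd.testing.assert_frame_equal(a, b)


class TestPiecewiseSem:
    def test_chain_recovery_single_replicate(self):
        bench = BenchSpec(paths=(("CI", "NLG", -0.6), ("res", "CI", -0.5)),
                          random_sd=0.3, n=300)
        fr = generate_benchmark(bench, seed=8)
        dag = nx.DiGraph([("NLG", "CI"), ("CI", "res"), ("NLG", "res")])
        pm = fit_piecewise_sem(fr, dag)
        assert set(pm.graph.edges) == {("NLG", "CI"), ("CI", "res")}
        assert pm.coef("NLG", "CI") == pytest.approx(-0.6, abs=0.15)
        assert pm.coef("CI", "res") == pytest.approx(-0.5, abs=0.15)

    def test_null_elimination(self):
        # saturated model on independent noise: elimination empties the
        # model in most replicates (the minimum of three p-values stays
        # below alpha with probability ~1 - 0.95^3, so not in all)
        empty = 0
        retained = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            fr = pd.DataFrame(rng.standard_normal((120, 3)),
                              columns=["a", "b", "c"])
            fr["ecosystem_type"] = np.tile([f"t{k}" for k in range(6)], 20)
            dag = nx.DiGraph([("a", "b"), ("a", "c"), ("b", "c")])
            pm = fit_piecewise_sem(fr, dag)
            retained += pm.graph.number_of_edges()
            empty += int(pm.graph.number_of_edges() == 0)
        assert empty >= 10
        assert retained / (20 * 3) <= 0.20

    def test_cyclic_dag_rejected(self):
        fr = pd.DataFrame(np.random.default_rng(0).standard_normal((50, 2)),
                          columns=["a", "b"])
        fr["ecosystem_type"] = "t0"
        with pytest.raises(ValueError, match="cycle"):
            fit_piecewise_sem(fr, nx.DiGraph([("a", "b"), ("b", "a")]))

    def test_default_dag_shape(self):
        g = default_dag("log_resistance")
        assert nx.is_directed_acyclic_graph(g)
        assert ("log_NLG", "log_resistance") in g.edges
        assert g.out_degree("log_NLG") == 4


class TestMediation:
    @pytest.fixture(scope="class")
    def fitted(self):
        bench = BenchSpec(paths=(("CI", "NLG", -0.6), ("res", "CI", -0.5)),
                          random_sd=0.3, n=300)
        fr = generate_benchmark(bench, seed=8)
        dag = nx.DiGraph([("NLG", "CI"), ("CI", "res"), ("NLG", "res")])
        return fr, fit_piecewise_sem(fr, dag)

    def test_product_rule_and_identity(self, fitted):
        fr, pm = fitted
        med = mediation(pm, fr, "NLG", "CI", "res", n_boot=0)
        a, b = pm.coef("NLG", "CI"), pm.coef("CI", "res")
        assert med["indirect"] == pytest.approx(a * b, rel=1e-12)
        assert med["total"] == med["direct"] + med["indirect"]
        assert med["indirect"] == pytest.approx(0.30, abs=0.1)

    def test_eliminated_direct_path_is_zero(self, fitted):
        fr, pm = fitted
        med = mediation(pm, fr, "NLG", "CI", "res", n_boot=0)
        assert med["direct"] == 0.0

    def test_null_mediator_ci_covers_zero(self):
        rng = np.random.default_rng(12)
        fr = pd.DataFrame({"NLG": rng.standard_normal(200),
                           "CI": rng.standard_normal(200)})
        fr["res"] = 0.5 * fr["NLG"] + rng.standard_normal(200)
        fr["ecosystem_type"] = np.tile([f"t{k}" for k in range(5)], 40)
        dag = nx.DiGraph([("NLG", "CI"), ("CI", "res"), ("NLG", "res")])
        pm = fit_piecewise_sem(fr, dag, alpha=1.1)  # keep all paths
        med = mediation(pm, fr, "NLG", "CI", "res", n_boot=200, seed=0)
        lo, hi = med["indirect_ci"]
        assert lo <= 0.0 <= hi


class TestQuantilePartialCorrelation:
    def test_shape_and_stability_on_common_signal(self):
        rng = np.random.default_rng(3)
        n = 250
        driver = rng.standard_normal(n)
        ind = pd.DataFrame({
            "i1": driver + 0.5 * rng.standard_normal(n),
            "i2": rng.standard_normal(n),
        })
        q = pd.DataFrame({
            f"q{p}": 0.8 * driver + 0.4 * rng.standard_normal(n)
            for p in range(0, 105, 5)
        })
        out = quantile_partial_correlation(q, ind)
        assert out.shape == (21, 2)
        spread = out["i1"].max() - out["i1"].min()
        assert spread <= 0.3  # stable across quantiles (+-0.15)

    def test_collinear_controls_flagged(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(50)
        ind = pd.DataFrame({"i1": x, "i2": x, "i3": rng.standard_normal(50)})
        q = pd.DataFrame({"q50": rng.standard_normal(50)})
        out = quantile_partial_correlation(q, ind)
        # i3's controls (i1, i2) are perfectly collinear -> rank-flagged
        assert np.isnan(out.loc["q50", "i3"])
        # i1's control set contains i2 = i1 duplicate -> residual degenerate
        assert np.isnan(out.loc["q50", "i1"]) and np.isnan(out.loc["q50", "i2"])


class TestGroupCompare:
    def test_identical_groups_share_letter(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, 90)
        grp = np.repeat(["a_t", "b_t", "c_t"], 30)
        out = group_compare(vals, grp)
        assert out["letters"].nunique() == 1

    def test_shifted_group_gets_distinct_letter(self):
        rng = np.random.default_rng(1)
        vals = np.r_[rng.normal(0, 1, 60), rng.normal(3, 1, 30)]
        grp = np.r_[np.repeat(["a_t", "b_t"], 30), np.repeat("c_t", 30)]
        out = group_compare(vals, grp).set_index("group")
        assert out.loc["c_t", "letters"] != out.loc["a_t", "letters"]
        assert out.loc["a_t", "letters"] == out.loc["b_t", "letters"]

    def test_two_groups_match_t_test(self):
        from scipy import stats as sps

        rng = np.random.default_rng(2)
        vals = np.r_[rng.normal(0, 1, 40), rng.normal(1.2, 1, 40)]
        grp = np.repeat(["a_t", "b_t"], 40)
        out = group_compare(vals, grp).set_index("group")
        p = sps.ttest_ind(vals[:40], vals[40:]).pvalue
        differs = out.loc["a_t", "letters"] != out.loc["b_t", "letters"]
        assert differs == (p < 0.05)
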