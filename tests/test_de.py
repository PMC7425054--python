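"""Size factors, dispersion estimation, the NB Wald test and DEG calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import comboseq as cs
from comboseq.de import CountMatrixError

from conftest import make_de_result


def _cm(counts: dict, conditions: dict) -> cs.CountMatrix:
    df = pd.DataFrame(counts)
    df.index = [f"g{i}" for i in range(len(df))]
    meta = pd.DataFrame(
        {
            "cell_line": "L1",
            "condition": pd.Series(conditions),
            "replicate": 1,
        }
    )
    return cs.CountMatrix(df.astype(np.int64), meta)


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        cm = _cm({"s1": [10, 20, 30], "s2": [10, 20, 30]},
                 {"s1": "control", "s2": "monoA"})
        f = cs.size_factors(cm)
        assert np.allclose(f, [1.0, 1.0])

    def test_hand_computed_two_sample_case(self):
        # geometric means sqrt(200), sqrt(800), sqrt(1800); medians of
        # ratios give (1/sqrt(2), sqrt(2))
        cm = _cm({"s1": [10, 20, 30], "s2": [20, 40, 60]},
                 {"s1": "control", "s2": "monoA"})
        f = cs.size_factors(cm)
        assert f["s1"] == pytest.approx(1 / math.sqrt(2), rel=1e-12)
        assert f["s2"] == pytest.approx(math.sqrt(2), rel=1e-12)

    def test_single_sample_is_one(self):
        df = pd.DataFrame({"s1": [5, 7, 9]}, index=["g0", "g1", "g2"])
        assert cs.size_factors(df).tolist() == [1.0]

    def test_all_genes_with_zeros_need_fallback(self):
        df = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]}, index=["g0", "g1"])
        with pytest.raises(CountMatrixError, match="fallback"):
            cs.size_factors(df, fallback=False)
        f = cs.size_factors(df, fallback=True)
        assert (f > 0).all()


class TestBHAdjust:
    def test_hand_computed_stepup(self):
        assert np.allclose(cs.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate_vectors(self):
        assert cs.bh_adjust([0.3]).tolist() == [0.3]
        assert cs.bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_missing_values_excluded_from_m(self):
        out = cs.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        # m=2: adj = min over j>=rank of p_(j) * 2 / j
        assert out[0] == pytest.approx(0.02)
        assert out[2] == pytest.approx(0.04)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cs.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_brute_force_stepup(self, ps):
        got = cs.bh_adjust(ps)
        m = len(ps)
        order = np.argsort(ps, kind="stable")
        expected = np.empty(m)
        for rank_pos, idx in enumerate(order, start=1):
            # min over all j >= rank of p_(j) * m / j
            expected[idx] = min(
                min(ps[order[j - 1]] * m / j for j in range(rank_pos, m + 1)),
                1.0,
            )
        assert np.allclose(got, expected)


class TestDispersion:
    def test_constant_counts_hit_the_floor(self):
        df = pd.DataFrame({f"s{i}": [50, 7] for i in range(4)},
                          index=["g0", "g1"])
        groups = pd.Series({f"s{i}": "a" for i in range(4)})
        d = cs.estimate_dispersion(df, factors=pd.Series(1.0, index=df.columns),
                                   groups=groups, shrink=False)
        assert (d <= 1e-8).all()

    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.poisson(100.0, size=(100, 1000)))
        df.columns = [f"s{i}" for i in df.columns]
        groups = pd.Series("a", index=df.columns)
        d = cs.estimate_dispersion(df, factors=pd.Series(1.0, index=df.columns),
                                   groups=groups, shrink=False)
        assert (d < 0.05).all()

    def test_planted_dispersion_recovered_with_many_replicates(self):
        rng = np.random.default_rng(1)
        alpha, mu, n = 0.2, 100.0, 500
        r = 1 / alpha
        df = pd.DataFrame(rng.negative_binomial(r, r / (r + mu),
                                                size=(200, n)))
        df.columns = [f"s{i}" for i in df.columns]
        groups = pd.Series("a", index=df.columns)
        d = cs.estimate_dispersion(df, factors=pd.Series(1.0, index=df.columns),
                                   groups=groups, shrink=False)
        assert abs(float(d.mean()) - alpha) < 0.02
        assert (np.abs(d - alpha) < 0.05).mean() > 0.5

    def test_single_replicate_design_rejected(self):
        df = pd.DataFrame({"s1": [5], "s2": [9]}, index=["g0"])
        groups = pd.Series({"s1": "a", "s2": "b"})
        with pytest.raises(ValueError, match="replicates"):
            cs.estimate_dispersion(df, factors=pd.Series(1.0, index=df.columns),
                                   groups=groups)


class TestWald:
    def test_identical_groups_are_null(self):
        cm = _cm(
            {"c1": [10], "c2": [10], "c3": [10],
             "t1": [10], "t2": [10], "t3": [10]},
            {s: ("monoA" if s.startswith("t") else "control")
             for s in ("c1", "c2", "c3", "t1", "t2", "t3")},
        )
        res = cs.wald_test(cm, ("monoA", "control"),
                           factors=pd.Series(1.0, index=cm.sample_ids),
                           dispersions=pd.Series(0.0, index=cm.gene_ids))
        row = res.table.iloc[0]
        assert row["log2fc"] == pytest.approx(0.0, abs=1e-12)
        assert row["stat"] == pytest.approx(0.0, abs=1e-12)
        assert row["p_value"] == pytest.approx(1.0)

    def test_poisson_limit_matches_closed_form_and_glm_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        cm = _cm(
            {"c1": [4], "c2": [6], "c3": [5], "t1": [18], "t2": [22], "t3": [20]},
            {s: ("monoA" if s.startswith("t") else "control")
             for s in ("c1", "c2", "c3", "t1", "t2", "t3")},
        )
        res = cs.wald_test(cm, ("monoA", "control"),
                           factors=pd.Series(1.0, index=cm.sample_ids),
                           dispersions=pd.Series(0.0, index=cm.gene_ids))
        row = res.table.iloc[0]
        assert row["log2fc"] == pytest.approx(2.0, abs=1e-10)
        # independent oracle: direct Poisson GLM likelihood fit
        y = np.array([4, 6, 5, 18, 22, 20])
        X = np.column_stack([np.ones(6), np.array([0, 0, 0, 1, 1, 1])])
        fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert row["log2fc"] * math.log(2) == pytest.approx(fit.params[1],
                                                            abs=1e-8)
        assert row["p_value"] == pytest.approx(fit.pvalues[1], abs=1e-6)

    def test_all_zero_gene_is_filtered_and_out_of_bh(self):
        cm = _cm(
            {"c1": [0, 10, 30], "c2": [0, 12, 31],
             "t1": [0, 30, 31], "t2": [0, 28, 29]},
            {s: ("monoA" if s.startswith("t") else "control")
             for s in ("c1", "c2", "t1", "t2")},
        )
        res = cs.wald_test(cm, ("monoA", "control"),
                           factors=pd.Series(1.0, index=cm.sample_ids),
                           dispersions=pd.Series(0.01, index=cm.gene_ids))
        t = res.table
        assert t.loc["g0", "status"] == "filtered_all_zero"
        assert np.isnan(t.loc["g0", "p_value"])
        tested_p = t.loc[["g1", "g2"], "p_value"].to_numpy()
        assert np.allclose(t.loc[["g1", "g2"], "padj"],
                           cs.bh_adjust(tested_p))

    def test_one_group_all_zero_gets_pseudocount_estimate(self):
        cm = _cm(
            {"c1": [8], "c2": [12], "t1": [0], "t2": [0]},
            {s: ("monoA" if s.startswith("t") else "control")
             for s in ("c1", "c2", "t1", "t2")},
        )
        res = cs.wald_test(cm, ("monoA", "control"),
                           factors=pd.Series(1.0, index=cm.sample_ids),
                           dispersions=pd.Series(0.0, index=cm.gene_ids))
        row = res.table.iloc[0]
        assert bool(row["separated"])
        # (0 + 0.5)/2 over (20 + 0.5)/2
        assert row["log2fc"] == pytest.approx(math.log2(0.5 / 20.5))
        assert np.isfinite(row["p_value"])

    def test_scale_equivariance_under_size_factors(self, sim_data):
        # size factors absorb depth changes: rescaling one library moves
        # each fold change by far less than its standard error (the GLM
        # weights that library by its depth, so the absorption is exact
        # only in the equal-weight limit), and rescaling every library
        # leaves fold changes essentially untouched.
        cm, _, _ = sim_data
        sub = cm.subset(conditions=("control", "monoA"))
        res1 = cs.wald_test(sub, ("monoA", "control"))
        disp = cs.estimate_dispersion(sub, factors=cs.size_factors(sub))
        scaled = sub.counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 4
        cm2 = cs.CountMatrix(scaled, sub.sample_meta.copy())
        res2 = cs.wald_test(cm2, ("monoA", "control"), dispersions=disp)
        d = (res1.table["log2fc"] - res2.table["log2fc"]).abs()
        rel = (d / res1.table["se"]).dropna()
        assert float(rel.max()) < 1.0
        assert float(d.dropna().mean()) < 0.05
        cm3 = cs.CountMatrix((sub.counts * 3).astype(np.int64),
                             sub.sample_meta.copy())
        res3 = cs.wald_test(cm3, ("monoA", "control"), dispersions=disp)
        d3 = (res1.table["log2fc"] - res3.table["log2fc"]).abs()
        assert float(d3.dropna().max()) < 0.05


class TestCallDegs:
    RESULT = None

    def setup_method(self):
        self.result = make_de_result([
            ("up_strong", 1.5, 0.001, 0.04),
            ("up_weak", 0.9, 0.001, 0.04),
            ("down_boundary", -1.0, 0.02, 0.05),
            ("not_sig", 2.5, 0.2, 0.6),
        ])

    def test_threshold_rule_with_inclusive_boundaries(self):
        degs = cs.call_degs(self.result, alpha=0.05, min_abs_lfc=1.0)
        assert degs.genes == {"up_strong", "down_boundary"}
        up = cs.call_degs(self.result, direction="up")
        down = cs.call_degs(self.result, direction="down")
        assert up.genes == {"up_strong"}
        assert down.genes == {"down_boundary"}

    def test_raw_p_mode(self):
        degs = cs.call_degs(self.result, alpha=0.01, p_column="raw")
        assert degs.genes == {"up_strong"}

    def test_tightening_thresholds_never_grows_the_set(self, de_results):
        res = de_results["comboA"]
        loose = cs.call_degs(res, alpha=0.1, min_abs_lfc=0.5)
        tight_alpha = cs.call_degs(res, alpha=0.01, min_abs_lfc=0.5)
        tight_lfc = cs.call_degs(res, alpha=0.1, min_abs_lfc=1.5)
        assert tight_alpha.genes <= loose.genes
        assert tight_lfc.genes <= loose.genes
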