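"""Tree building, BM ancestral states, branch rates and line summaries."""

import numpy as np
import pandas as pd
import pytest

from conftest import simulate_bm_tips
from oracles import bm_states_bruteforce, exact_binomial_two_sided
from satrate import (
    GenerationTree,
    ancestral_bm,
    branch_rates,
    build_tree,
    per_line_summary,
    per_unit_summary,
    sign_test,
    years_to_generations,
)


class TestBuildTree:
    def test_years_to_generations_half_up(self):
        # 50 years x 4.33 = 216.5 -> 217
        assert years_to_generations(50) == 217
        assert years_to_generations(100) == 433

    def test_pedigree_records_two_lines(self):
        records = pd.DataFrame(
            {"child": ["A", "B"], "parent": ["P", "P"], "split_years_ago": [50, 50]}
        )
        tree = build_tree(records=records, basal_split_generations=None)
        assert sorted(tree.tips) == ["A", "B"]
        for tip in ("A", "B"):
            assert tree.terminal_branch(tip)[1] == 217

    def test_newick_passthrough(self):
        tree = build_tree(newick="(A:100,B:200)r;", basal_split_generations=None)
        assert tree.terminal_branch("A")[1] == 100.0
        assert tree.terminal_branch("B")[1] == 200.0

    def test_basal_split_override(self):
        tree = build_tree(newick="((A:50,B:60)x:10,(C:70,D:80)y:10)r;",
                          basal_split_generations=850)
        root = tree.root_index()
        basal = [tree.length[i] for i, p in enumerate(tree.parent) if p == root]
        assert basal == [425.0, 425.0]
        # terminal branches untouched
        assert tree.terminal_branch("A")[1] == 50.0

    def test_non_ultrametric_records_rejected(self):
        records = pd.DataFrame(
            {
                "child": ["A", "C", "B"],
                "parent": ["P", "A", "P"],
                "split_years_ago": [50, 60, 50],  # C older than its parent A
            }
        )
        with pytest.raises(ValueError, match="non-ultrametric"):
            build_tree(records=records, basal_split_generations=None)

    def test_zero_length_branch_rejected(self):
        with pytest.raises(ValueError, match="branch lengths"):
            GenerationTree.from_newick("(A:0,B:10)r;")


class TestAncestralBM:
    def test_two_tip_equal_branches_root_is_mean(self):
        tree = GenerationTree.from_newick("(A:100,B:100)r;")
        tips = pd.DataFrame({"u": [100.0, 200.0]}, index=["A", "B"])
        assert ancestral_bm(tree, tips).at["r", "u"] == pytest.approx(150.0)

    def test_star_tree_root_is_mean(self):
        tree = GenerationTree.from_newick("(A:50,B:50,C:50,D:50)r;")
        tips = pd.DataFrame({"u": [1.0, 2.0, 3.0, 6.0]}, index=list("ABCD"))
        assert ancestral_bm(tree, tips).at["r", "u"] == pytest.approx(3.0)

    def test_two_tip_unequal_branches_precision_weighted(self):
        # minimize (x-0)^2/100 + (x-300)^2/200 -> x = 100
        tree = GenerationTree.from_newick("(A:100,B:200)r;")
        tips = pd.DataFrame({"u": [0.0, 300.0]}, index=["A", "B"])
        assert ancestral_bm(tree, tips).at["r", "u"] == pytest.approx(100.0)

    def test_tip_states_preserved_exactly(self, fixture_tree, rng):
        tips = simulate_bm_tips(fixture_tree, rng, n_units=3)
        anc = ancestral_bm(fixture_tree, tips)
        pd.testing.assert_frame_equal(anc.loc[tips.index], tips)

    def test_missing_tip_named_in_error(self, fixture_tree):
        tips = pd.DataFrame({"u": [1.0]}, index=["A1"])
        with pytest.raises(ValueError, match="A2"):
            ancestral_bm(fixture_tree, tips)

    def test_agrees_with_bruteforce_minimizer(self, fixture_tree, rng):
        tips = simulate_bm_tips(fixture_tree, rng, n_units=2)
        anc = ancestral_bm(fixture_tree, tips)
        for unit in tips.columns:
            ref = bm_states_bruteforce(
                fixture_tree.parent, fixture_tree.length, fixture_tree.is_tip,
                fixture_tree.labels, dict(tips[unit]),
            )
            for label, v in ref.items():
                assert anc.at[label, unit] == pytest.approx(v, rel=1e-6, abs=1e-6)

    def test_near_zero_pseudo_branch_leaves_states_unchanged(self):
        base = GenerationTree.from_newick("(A:100,(B:100,C:150)n1:50)r;")
        padded = GenerationTree.from_newick(
            "((A:100)p0:1e-8,(B:100,C:150)n1:50)r;"
        )
        tips = pd.DataFrame({"u": [10.0, 40.0, 90.0]}, index=["A", "B", "C"])
        a1 = ancestral_bm(base, tips)
        a2 = ancestral_bm(padded, tips)
        for node in ("r", "n1"):
            assert a2.at[node, "u"] == pytest.approx(a1.at[node, "u"], abs=1e-5)


class TestBranchRates:
    def two_tip_rates(self, a_val, anc_val, G):
        tree = GenerationTree.from_newick(f"(A:{G},B:{G})r;")
        tips = pd.DataFrame({"u": [a_val, 2 * anc_val - a_val]}, index=["A", "B"])
        ancestors = pd.DataFrame({"u": [anc_val]}, index=["r"])
        df = branch_rates(tree, tips, ancestors=ancestors)
        return df[df.line == "A"].iloc[0]

    def test_gain_rate_arithmetic(self):
        r = self.two_tip_rates(110.0, 100.0, 100)
        assert r.u == pytest.approx(0.1)
        assert r.normalized == pytest.approx(1.0e-3)
        assert r.absolute == pytest.approx(0.1)

    def test_no_change_gives_zero_rates(self):
        r = self.two_tip_rates(100.0, 100.0, 100)
        assert r.u == 0 and r.normalized == 0 and r.absolute == 0

    def test_loss_rate_sign(self):
        r = self.two_tip_rates(90.0, 100.0, 200)
        assert r.u == pytest.approx(-0.05)
        assert r.normalized == pytest.approx(-5.0e-4)
        assert r.absolute == pytest.approx(0.05)

    def test_normalized_na_below_one_ancestral_copy(self):
        r = self.two_tip_rates(1.0, 0.5, 100)
        assert np.isnan(r.normalized)
        assert np.isfinite(r.u)

    def test_rate_identity_u_equals_normalized_times_ancestor(self, fixture_tree, rng):
        tips = simulate_bm_tips(fixture_tree, rng, n_units=4)
        df = branch_rates(fixture_tree, tips)
        ok = df.ancestor >= 1.0
        np.testing.assert_allclose(
            df.loc[ok, "normalized"] * df.loc[ok, "ancestor"], df.loc[ok, "u"]
        )
        np.testing.assert_allclose(df.absolute, df.u.abs())


class TestPerLineSummary:
    def make_rates(self, n_gain, n_loss, n_zero=0):
        u = [1.0] * n_gain + [-1.0] * n_loss + [0.0] * n_zero
        return pd.DataFrame(
            {
                "line": "L",
                "unit": [f"u{i}" for i in range(len(u))],
                "u": u,
                "normalized": [x * 1e-3 for x in u],
                "absolute": [abs(x) for x in u],
                "G": 100.0,
                "ancestor": 1000.0,
            }
        )

    def test_sign_test_matches_exact_binomial_enumeration(self):
        s = per_line_summary(self.make_rates(50, 13)).iloc[0]
        assert s.sign_p == pytest.approx(exact_binomial_two_sided(50, 63), rel=1e-10)
        assert s.skewed

    def test_near_symmetric_counts_not_skewed(self):
        s = per_line_summary(self.make_rates(32, 31)).iloc[0]
        assert s.sign_p > 0.05
        assert not s.skewed

    def test_zeros_excluded_from_sign_test(self):
        s = per_line_summary(self.make_rates(10, 2, n_zero=51)).iloc[0]
        assert s.n_zero == 51
        assert s.sign_p == pytest.approx(exact_binomial_two_sided(10, 12), rel=1e-10)

    def test_all_zero_rates_give_na(self):
        s = per_line_summary(self.make_rates(0, 0, n_zero=5)).iloc[0]
        assert np.isnan(s.sign_p)
        assert not s.skewed

    def test_sign_test_nan_for_no_observations(self):
        assert np.isnan(sign_test(0, 0))


class TestPerUnitSummary:
    def test_constant_unit_ranks_last(self, fixture_tree, rng):
        tips = simulate_bm_tips(fixture_tree, rng, sigma=2.0, n_units=3)
        tips["flat"] = 500.0
        df = branch_rates(fixture_tree, tips)
        summary = per_unit_summary(df).set_index("unit")
        assert summary.at["flat", "mean_abs"] == pytest.approx(0.0, abs=1e-12)
        assert summary.at["flat", "rank"] == len(tips.columns)

    def test_single_diverged_line_mean_abs(self):
        tree = GenerationTree.from_newick("(A:100,B:100,C:100,D:100)r;")
        tips = pd.DataFrame({"u": [110.0, 100.0, 100.0, 100.0]}, index=list("ABCD"))
        anc = pd.DataFrame({"u": [100.0]}, index=["r"])
        df = branch_rates(tree, tips, ancestors=anc)
        summary = per_unit_summary(df)
        # one line at |u|/G/anc = 1e-3, three at 0
        assert summary.at[0, "mean_abs"] == pytest.approx(1e-3 / 4)
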