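"""Two-part statistic, Kruskal-Wallis screen and BH-FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from microdab import (
    TaxonCountTable,
    bh_fdr,
    kruskal_wallis,
    kruskal_wallis_screen,
    run_comparison,
    two_part_test,
)
from .conftest import brute_force_bh, permutation_two_part_p

abundances = st.lists(
    st.one_of(st.just(0.0), st.floats(0.001, 1.0, allow_nan=False)),
    min_size=2,
    max_size=12,
)


class TestTwoPart:
    def test_hand_worked_example(self):
        r = two_part_test([0, 0, 1, 2, 3], [4, 5, 6, 7, 8])
        assert r.zp_sq == pytest.approx(2.5)
        assert r.zw_sq == pytest.approx(5.0)
        assert r.statistic == pytest.approx(7.5)
        assert r.df == 2
        assert r.parts_used == "both"
        assert r.p_raw == pytest.approx(np.exp(-3.75), rel=1e-12)

    def test_identical_all_positive_groups_give_p_one(self):
        r = two_part_test([1, 2, 3], [1, 2, 3])
        assert r.statistic == 0.0
        assert r.df == 1
        assert r.parts_used == "wilcoxon_only"
        assert r.p_raw == 1.0

    def test_presence_only_branch_when_one_group_all_zero(self):
        r = two_part_test([0, 0, 0, 0], [1, 2, 1, 3])
        assert r.parts_used == "presence_only"
        assert r.df == 1
        assert np.isnan(r.zw_sq)

    def test_all_zero_both_groups_is_an_error(self):
        with pytest.raises(ValueError):
            two_part_test([0, 0], [0, 0], taxon="ghost")

    def test_needs_two_samples_per_group(self):
        with pytest.raises(ValueError):
            two_part_test([1], [1, 2])

    def test_wilcoxon_part_cross_checked_against_scipy(self):
        # both-parts instance: the rank-sum z on the nonzero values must
        # match scipy's asymptotic Mann-Whitney without continuity.
        rng = np.random.default_rng(5)
        for _ in range(25):
            x = rng.binomial(1, 0.8, 10) * rng.lognormal(0, 1, 10)
            y = rng.binomial(1, 0.8, 10) * rng.lognormal(0.3, 1, 10)
            xs, ys = x[x > 0], y[y > 0]
            if len(xs) == 0 or len(ys) == 0 or len(xs) == 10 and len(ys) == 10:
                continue
            r = two_part_test(x, y)
            mwu = stats.mannwhitneyu(
                xs, ys, alternative="two-sided", method="asymptotic",
                use_continuity=False,
            )
            z_sq = stats.norm.isf(mwu.pvalue / 2) ** 2
            assert r.zw_sq == pytest.approx(z_sq, rel=1e-8, abs=1e-10)

    @settings(max_examples=150, deadline=None)
    @given(abundances, abundances)
    def test_symmetry_in_group_order(self, x, y):
        if not any(v > 0 for v in x + y):
            return
        r_xy = two_part_test(x, y)
        r_yx = two_part_test(y, x)
        assert r_xy.statistic == pytest.approx(r_yx.statistic, abs=1e-10)
        assert r_xy.df == r_yx.df
        assert r_xy.p_raw == pytest.approx(r_yx.p_raw, abs=1e-12)

    @settings(max_examples=150, deadline=None)
    @given(abundances, abundances)
    def test_combined_statistic_dominates_each_part(self, x, y):
        if not any(v > 0 for v in x + y):
            return
        r = two_part_test(x, y)
        assert r.statistic >= 0
        if r.parts_used == "both":
            assert r.statistic == pytest.approx(r.zp_sq + r.zw_sq)
            assert r.statistic >= max(r.zp_sq, r.zw_sq) - 1e-12
        assert 0 < r.p_raw <= 1

    def test_exact_wilcoxon_flag_matches_enumeration(self):
        # tie-free small instance: the exact flag must reproduce the
        # enumerated two-sided rank-sum p inside the abundance part
        x = [0, 0, 0.11, 0.23, 0.35, 0.41]
        y = [0.52, 0.64, 0.70, 0.86, 0.93, 0.12]
        r = two_part_test(x, y, exact_wilcoxon=True)
        xs = np.array([v for v in x if v > 0])
        ys = np.array([v for v in y if v > 0])
        p_exact = stats.mannwhitneyu(
            xs, ys, alternative="two-sided", method="exact"
        ).pvalue
        z = stats.norm.isf(p_exact / 2)
        assert r.zw_sq == pytest.approx(z**2, rel=1e-10)
        assert r.parts_used == "both"

    def test_exact_and_asymptotic_agree_on_direction(self):
        x = [0.1, 0.2, 0.3, 0.4]
        y = [0.5, 0.6, 0.7, 0.8]
        r_asym = two_part_test(x, y)
        r_exact = two_part_test(x, y, exact_wilcoxon=True)
        assert r_asym.parts_used == r_exact.parts_used == "wilcoxon_only"
        assert r_asym.statistic > 0 and r_exact.statistic > 0

    def test_permutation_oracle_spot_check(self):
        # one moderate instance: asymptotic p within a loose band of the
        # relabeling distribution (the fine-grained sweep lives in the
        # acceptance suite).
        rng = np.random.default_rng(11)
        x = rng.binomial(1, 0.8, 8) * rng.lognormal(0, 1, 8)
        y = rng.binomial(1, 0.8, 8) * rng.lognormal(1.0, 1, 8)
        obs, perm = permutation_two_part_p(x, y, 20000, rng)
        assert perm == pytest.approx(obs, abs=0.08)


class TestRunComparison:
    def test_bloom_taxon_tops_the_ranking(self):
        from microdab import bloom_study_config, simulate_counts
        from microdab.simulate import BLOOM_TAXON

        table, _ = simulate_counts(bloom_study_config(seed=42))
        results = run_comparison(table, "treatment", "control")
        assert results[0].taxon == BLOOM_TAXON
        assert results[0].p_adj <= results[0].p_raw * len(results)

    def test_results_sorted_and_adjusted_within_retained_set(self, toy_table):
        results = run_comparison(toy_table, "A", "B")
        ps = [r.p_raw for r in results]
        assert ps == sorted(ps)
        expected = brute_force_bh(ps)
        for r, e in zip(results, expected):
            assert r.p_adj == pytest.approx(e)

    def test_taxon_failing_prevalence_filter_is_not_tested(self, toy_table):
        tested = {r.taxon for r in run_comparison(toy_table, "A", "B")}
        assert "taxD" not in tested  # present in 1/4 of B only

    def test_rare_taxa_drop_out_under_strict_filter(self):
        index = [f"s{i}" for i in range(8)]
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=index)
        table = TaxonCountTable(
            pd.DataFrame(
                {"t1": [4, 1, 0, 0, 0, 0, 0, 0],
                 "t2": [1, 1, 1, 1, 1, 1, 1, 1]},
                index=index,
            ),
            groups,
        )
        results = run_comparison(table, "A", "B", min_prop=0.9)
        assert [r.taxon for r in results] == ["t2"]

    def test_empty_result_when_nothing_passes_filter(self):
        index = [f"s{i}" for i in range(8)]
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=index)
        table = TaxonCountTable(
            pd.DataFrame(
                {"t1": [4, 0, 0, 0, 1, 0, 0, 0],
                 "t2": [1, 1, 0, 0, 0, 0, 1, 1]},
                index=index,
            ),
            groups,
        )
        assert run_comparison(table, "A", "B", min_prop=0.75) == []

    def test_too_small_group_is_an_error(self):
        counts = pd.DataFrame({"t": [1, 1, 1]}, index=["s1", "s2", "s3"])
        groups = pd.Series({"s1": "A", "s2": "B", "s3": "B"})
        with pytest.raises(ValueError):
            run_comparison(TaxonCountTable(counts, groups), "A", "B")


class TestKruskalWallis:
    def test_textbook_rank_example(self):
        r = kruskal_wallis({"g1": [1, 2, 3], "g2": [4, 5, 6]})
        assert r.h == pytest.approx(3.857142857, rel=1e-6)
        assert r.df == 1
        assert r.p_raw == pytest.approx(0.0495, abs=5e-4)

    def test_total_tie_convention(self):
        r = kruskal_wallis({"g1": [2.0, 2.0], "g2": [2.0, 2.0]})
        assert r.h == 0.0
        assert r.p_raw == 1.0

    def test_single_group_is_an_error(self):
        with pytest.raises(ValueError):
            kruskal_wallis({"only": [1, 2, 3]})

    def test_screen_covers_all_nonzero_taxa(self, toy_table):
        results = kruskal_wallis_screen(toy_table)
        assert {r.taxon for r in results} == set(toy_table.taxa)
        ps = [r.p_raw for r in results]
        assert ps == sorted(ps)

    def test_null_rejection_rate_small_sample(self):
        # 300 replicates of 3 null groups; the acceptance suite runs the
        # full 2,000-replicate calibration.
        rng = np.random.default_rng(3)
        rejections = 0
        for _ in range(300):
            groups = {g: rng.lognormal(0, 1, 6) for g in "abc"}
            rejections += kruskal_wallis(groups).p_raw < 0.05
        assert 0.02 <= rejections / 300 <= 0.09


class TestBH:
    def test_equal_spacing_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.5]) == pytest.approx([0.5])

    def test_empty_list(self):
        assert len(bh_fdr([])) == 0

    def test_all_permutations_of_length_six_match_brute_force(self):
        base = [0.011, 0.22, 0.013, 0.8, 0.047, 0.047]
        for perm in itertools.permutations(base):
            assert bh_fdr(list(perm)) == pytest.approx(brute_force_bh(list(perm)))

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(1e-9, 1.0, allow_nan=False), min_size=1, max_size=20))
    def test_random_lists_match_brute_force(self, ps):
        assert bh_fdr(ps) == pytest.approx(brute_force_bh(ps))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
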