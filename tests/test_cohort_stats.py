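"""Rank tests, subgrouping, angular summaries and the dip statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from oracles import (
    dip_oracle_lp,
    dunn_perm_pvalue,
    dunn_z_oracle,
    kw_perm_pvalue,
    kw_statistic_oracle,
)
from villimorph.cohort_stats import (
    GroupedSample,
    angular_modes,
    dip_test_pvalue,
    dunns_posthoc,
    hartigan_dip,
    kruskal_wallis,
    rose_histogram,
    significance_stars,
    split_ht_lt,
    two_sample_t,
)


class TestKruskalWallis:
    def test_identical_groups_give_h0_p1(self):
        s = GroupedSample.from_groups({"a": [1, 2, 3], "b": [1, 2, 3]})
        res = kruskal_wallis(s)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_rank_sums(self):
        # ranks 1..6, rank sums R1=6, R2=15 -> H = 27/7
        s = GroupedSample.from_groups({"a": [1, 2, 3], "b": [4, 5, 6]})
        res = kruskal_wallis(s)
        assert res.statistic == pytest.approx(12 / 42 * (36 / 3 + 225 / 3) - 21, rel=1e-12)
        assert res.statistic == pytest.approx(27 / 7, rel=1e-12)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(4)
        a, b, c = (np.round(rng.normal(size=n), 1) for n in (12, 9, 15))
        s = GroupedSample.from_groups({"a": a, "b": b, "c": c})
        res = kruskal_wallis(s)
        ref = sps.kruskal(a, b, c)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_all_constant_data(self):
        s = GroupedSample.from_groups({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        res = kruskal_wallis(s)
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=20)
        labels = np.repeat(["a", "b"], 10)
        p1 = kruskal_wallis(GroupedSample(vals, labels)).p_value
        p2 = kruskal_wallis(GroupedSample(np.exp(vals), labels)).p_value
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_permutation_oracle_agreement(self):
        # 15 per group: large enough that the chi-square approximation error
        # is dominated by the oracle's Monte-Carlo error
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            vals = rng.normal(size=45) + np.repeat([0.0, 0.6, 0.2], 15)
            labels = np.repeat(["a", "b", "c"], 15)
            res = kruskal_wallis(GroupedSample(vals, labels))
            p_perm, se = kw_perm_pvalue(vals, labels, n_perm=2000, seed=100 + seed)
            assert abs(res.p_value - p_perm) <= 3 * se

    def test_statistic_equals_independent_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            sizes = rng.integers(3, 8, size=3)
            vals = np.round(rng.normal(size=sizes.sum()), 1)
            labels = np.repeat(["a", "b", "c"], sizes)
            mine = kruskal_wallis(GroupedSample(vals, labels)).statistic
            assert mine == pytest.approx(kw_statistic_oracle(vals, labels), rel=1e-12)


class TestDunn:
    def test_two_groups_rejected(self):
        s = GroupedSample.from_groups({"a": [1, 2], "b": [3, 4]})
        with pytest.raises(ValueError, match="omnibus"):
            dunns_posthoc(s)

    def test_identical_groups_all_p_one(self):
        s = GroupedSample.from_groups({g: [1, 2, 3] for g in "abc"})
        res = dunns_posthoc(s)
        assert all(p["p_adj"] == pytest.approx(1.0) for p in res.pairwise)

    def test_extreme_pair_has_largest_z(self):
        s = GroupedSample.from_groups({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        res = dunns_posthoc(s, "none")
        by_pair = {tuple(p["groups"]): abs(p["z"]) for p in res.pairwise}
        assert by_pair[("a", "c")] > by_pair[("a", "b")]
        assert by_pair[("a", "c")] > by_pair[("b", "c")]
        # |z| ordering matches mean-rank gaps
        assert by_pair[("a", "b")] == pytest.approx(by_pair[("b", "c")], rel=1e-12)

    def test_bonferroni_is_m_times_p(self):
        rng = np.random.default_rng(3)
        s = GroupedSample.from_groups(
            {g: rng.normal(i, 1, 7) for i, g in enumerate("abc")}
        )
        raw = dunns_posthoc(s, "none")
        bon = dunns_posthoc(s, "bonferroni")
        for pr, pb in zip(raw.pairwise, bon.pairwise):
            assert pb["p_adj"] == pytest.approx(min(1.0, 3 * pr["p_raw"]), rel=1e-12)
            assert pb["p_adj"] >= pr["p_raw"]

    def test_holm_never_exceeds_bonferroni(self):
        rng = np.random.default_rng(8)
        s = GroupedSample.from_groups(
            {g: rng.normal(i * 0.5, 1, 9) for i, g in enumerate("abcd")}
        )
        holm = dunns_posthoc(s, "holm")
        bon = dunns_posthoc(s, "bonferroni")
        for ph, pb in zip(holm.pairwise, bon.pairwise):
            assert ph["p_adj"] <= pb["p_adj"] + 1e-12
            assert ph["p_adj"] >= ph["p_raw"]

    def test_permutation_oracle_agreement(self):
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            vals = rng.normal(size=45) + np.repeat([0.0, 0.6, 0.2], 15)
            labels = np.repeat(["a", "b", "c"], 15)
            res = dunns_posthoc(GroupedSample(vals, labels), "none")
            for pair in res.pairwise:
                a, b = pair["groups"]
                p_perm, se = dunn_perm_pvalue(
                    vals, labels, a, b, n_perm=2000, seed=200 + seed
                )
                assert abs(pair["p_raw"] - p_perm) <= 3 * se

    def test_z_equals_independent_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            sizes = rng.integers(3, 8, size=3)
            vals = np.round(rng.normal(size=sizes.sum()), 1)
            labels = np.repeat(["a", "b", "c"], sizes)
            res = dunns_posthoc(GroupedSample(vals, labels), "none")
            for pair in res.pairwise:
                a, b = pair["groups"]
                assert pair["z"] == pytest.approx(
                    dunn_z_oracle(vals, labels, a, b), rel=1e-12
                )


class TestTwoSampleT:
    def test_identical_samples(self):
        res = two_sample_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_separation_limit(self):
        res = two_sample_t([0, 0, 0, 1e-9], [1, 1, 1, 1 + 1e-9])
        assert res.p_value < 1e-10

    def test_textbook_pooled_value(self):
        # means 2.5 vs 4.5, pooled variance 5/3 -> t = -2/sqrt(5/6)
        res = two_sample_t([1, 2, 3, 4], [3, 4, 5, 6])
        assert res.statistic == pytest.approx(-2.0 / np.sqrt(5.0 / 6.0), rel=1e-12)
        assert res.statistic == pytest.approx(-2.1908902, rel=1e-6)
        ref = sps.ttest_ind([1, 2, 3, 4], [3, 4, 5, 6])
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 11), rng.normal(0.5, 3, 7)
        res = two_sample_t(a, b, welch=True)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_degenerate_zero_variance(self):
        res = two_sample_t([1.0, 1.0], [2.0, 2.0])
        assert res.p_value == 0.0 and "degenerate" in res.method
        res = two_sample_t([1.0, 1.0], [1.0, 1.0])
        assert res.p_value == 1.0


class TestSplitHtLt:
    def test_above_threshold_is_ht(self):
        assert split_ht_lt({"s": 1.25}) == {"s": "HT-normal"}

    def test_below_threshold_is_lt(self):
        assert split_ht_lt({"s": 1.05}) == {"s": "LT-normal"}

    def test_exact_threshold_is_lt_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            labels = split_ht_lt({"s": 1.2})
        assert labels == {"s": "LT-normal"}
        assert any("cutoff" in r.message for r in caplog.records)

    def test_missing_value_excluded(self, caplog):
        with caplog.at_level("WARNING"):
            labels = split_ht_lt({"s": None, "t": 1.3})
        assert labels == {"t": "HT-normal"}

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            split_ht_lt({"s": 1.1}, threshold=0.9)


class TestRoseHistogram:
    def test_single_sector(self):
        edges, counts = rose_histogram([45.0] * 10, bin_width=10.0)
        assert counts.sum() == 10
        assert counts[4] == 10 and (counts != 0).sum() == 1

    def test_counts_conserved(self):
        rng = np.random.default_rng(1)
        angles = rng.uniform(0, 180, 57)
        _, counts = rose_histogram(angles, 15.0)
        assert counts.sum() == 57

    def test_uniform_grid_equal_counts(self):
        angles = np.arange(5.0, 180.0, 10.0)  # one per 10-degree sector
        _, counts = rose_histogram(angles, 10.0)
        assert set(counts[:18]) == {1} and counts[18:].sum() == 0

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            rose_histogram([10.0], bin_width=7.0)


class TestAngularModes:
    def test_two_tight_clusters(self):
        rng = np.random.default_rng(0)
        angles = np.concatenate([rng.normal(52, 1.0, 40), rng.normal(66, 1.0, 40)])
        modes = angular_modes(angles, bandwidth=4.0)
        assert len(modes) == 2
        assert modes[0] == pytest.approx(52, abs=1.0)
        assert modes[1] == pytest.approx(66, abs=1.0)

    def test_single_cluster(self):
        rng = np.random.default_rng(1)
        modes = angular_modes(rng.normal(67, 1.5, 50), bandwidth=4.0)
        assert len(modes) == 1
        assert modes[0] == pytest.approx(67, abs=1.0)

    def test_constant_sample(self):
        modes = angular_modes([58.0] * 10, bandwidth=4.0)
        assert modes == [58.0]

    def test_modes_never_closer_than_bandwidth(self):
        rng = np.random.default_rng(2)
        for bw in (2.0, 4.0, 8.0):
            angles = rng.uniform(0, 180, 60)
            modes = angular_modes(angles, bandwidth=bw)
            assert all(b - a >= bw for a, b in zip(modes, modes[1:]))


class TestHartiganDip:
    def test_equally_spaced_minimum(self):
        assert hartigan_dip([1.0, 2.0, 3.0, 4.0]) == pytest.approx(0.125, abs=1e-12)

    def test_two_spike_maximum(self):
        sample = np.repeat([0.0, 1.0], 25)
        assert hartigan_dip(sample) == pytest.approx(0.25, abs=1e-12)

    def test_constant_sample_is_zero(self):
        assert hartigan_dip([3.0] * 8) == 0.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_bounds(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        x = rng.normal(size=n)
        d = hartigan_dip(x)
        assert 0.0 <= d <= 0.25 + 1e-12

    def test_scale_and_shift_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        d = hartigan_dip(x)
        assert hartigan_dip(5.0 * x - 3.0) == pytest.approx(d, abs=1e-12)

    def test_small_n_battery_matches_lp_oracle(self):
        # >= 100 seeded samples with n <= 8, including ties and bimodal shapes
        rng = np.random.default_rng(12345)
        checked = 0
        while checked < 110:
            n = int(rng.integers(4, 9))
            kind = checked % 3
            if kind == 0:
                s = rng.normal(size=n)
            elif kind == 1:
                s = np.round(rng.normal(size=n) * 2) / 2
            else:
                s = np.concatenate(
                    [rng.normal(-3, 0.3, n // 2), rng.normal(3, 0.3, n - n // 2)]
                )
            assert hartigan_dip(s) == pytest.approx(dip_oracle_lp(s), abs=1e-7)
            checked += 1


class TestDipPvalue:
    def test_uniform_sample_not_significant(self):
        rng = np.random.default_rng(0)
        res = dip_test_pvalue(rng.uniform(size=200), n_boot=1000, seed=1)
        assert res.p_value > 0.2

    def test_bimodal_sample_significant(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 0.05, 45), rng.normal(1, 0.05, 45)])
        res = dip_test_pvalue(x, n_boot=1000, seed=1)
        assert res.p_value < 0.05

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        p1 = dip_test_pvalue(x, n_boot=1000, seed=7).p_value
        p2 = dip_test_pvalue(100.0 * x + 17.0, n_boot=1000, seed=7).p_value
        assert p1 == p2

    def test_requires_minimum_bootstrap(self):
        with pytest.raises(ValueError):
            dip_test_pvalue([1, 2, 3, 4], n_boot=10)


def test_significance_star_thresholds():
    assert [significance_stars(p) for p in (0.5, 0.04, 0.009, 0.0009)] == [
        "", "*", "**", "***",
    ]
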