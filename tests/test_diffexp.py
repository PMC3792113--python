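import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import oncoscreen as osc
from oncoscreen.diffexp import _ttest_rows


def pooled_t(a, b):
    """Textbook pooled-variance two-sample t — independent oracle."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    return (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))


class TestGeneTTest:
    def test_textbook_fixture(self):
        # pooled t on {4,5,6} vs {1,2,3}: t = 3/sqrt(2/3) = 3.674, df = 4
        t, p = osc.gene_t_test([4, 5, 6], [1, 2, 3], log_transform=False)
        assert t == pytest.approx(3.674, abs=1e-3)
        assert p == pytest.approx(0.0213, abs=1e-4)
        assert t == pytest.approx(pooled_t([4, 5, 6], [1, 2, 3]))

    def test_log2_applied_internally(self):
        # feeding 2**x with the default transform equals testing x directly
        t_lin, p_lin = osc.gene_t_test(2.0 ** np.array([4, 5, 6]), 2.0 ** np.array([1, 2, 3]))
        t_ref, p_ref = osc.gene_t_test([4, 5, 6], [1, 2, 3], log_transform=False)
        assert (t_lin, p_lin) == pytest.approx((t_ref, p_ref))

    def test_identical_constant_groups_give_no_difference(self):
        t, p = osc.gene_t_test([5, 5, 5], [5, 5, 5])
        assert (t, p) == (0.0, 1.0)

    def test_swapping_groups_negates_t_only(self):
        t1, p1 = osc.gene_t_test([4, 5, 6], [1, 2, 3], log_transform=False)
        t2, p2 = osc.gene_t_test([1, 2, 3], [4, 5, 6], log_transform=False)
        assert t2 == pytest.approx(-t1) and p2 == pytest.approx(p1)

    def test_missing_values_dropped(self):
        t1, _ = osc.gene_t_test([4, 5, 6, np.nan], [1, 2, 3], log_transform=False)
        t2, _ = osc.gene_t_test([4, 5, 6], [1, 2, 3], log_transform=False)
        assert t1 == pytest.approx(t2)

    def test_too_few_values_flagged(self):
        with pytest.raises(osc.StudyValidationError):
            osc.gene_t_test([4, np.nan], [1, 2, 3])

    def test_constant_groups_with_different_means(self):
        t, p = osc.gene_t_test([8, 8, 8], [2, 2, 2])
        assert t == np.inf and 0 < p <= 1e-300

    @given(
        st.lists(st.floats(1.0, 100.0), min_size=3, max_size=8),
        st.lists(st.floats(1.0, 100.0), min_size=3, max_size=8),
    )
    def test_matches_textbook_oracle(self, a, b):
        if np.var(a) + np.var(b) == 0:
            return
        t, p = osc.gene_t_test(a, b, log_transform=False)
        assert t == pytest.approx(pooled_t(a, b), rel=1e-9)
        assert 0 < p <= 1


class TestFoldChange:
    @pytest.mark.parametrize(
        "cancer, normal, expected",
        [([20, 20], [10, 10], 2.0), ([10, 10], [20, 20], -2.0), ([7, 7], [7, 7], 1.0)],
    )
    def test_signed_linear_convention(self, cancer, normal, expected):
        assert osc.fold_change(cancer, normal) == pytest.approx(expected)

    def test_reciprocal_antisymmetry(self):
        fc = osc.fold_change([30, 34], [9, 11])
        rev = osc.fold_change([9, 11], [30, 34])
        assert rev == pytest.approx(-fc)

    def test_magnitude_at_least_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b = rng.uniform(0.5, 50, 4), rng.uniform(0.5, 50, 4)
            assert abs(osc.fold_change(a, b)) >= 1.0

    def test_non_positive_mean_undefined(self):
        assert np.isnan(osc.fold_change([-1.0, 1.0], [1.0, 1.0]))


class TestRankAndPercentile:
    def test_single_gene(self):
        rp = osc.rank_and_percentile(pd.Series({"KCNK1": 0.5}))
        assert rp.loc["KCNK1", "rank"] == 1 and rp.loc["KCNK1", "percentile"] == 100

    def test_percentile_is_ceiling(self):
        p = pd.Series(np.linspace(1e-6, 1, 14000), index=[f"g{i:05d}" for i in range(14000)])
        rp = osc.rank_and_percentile(p)
        assert rp["percentile"].iloc[139] == 1  # rank 140 of 14000
        assert rp["percentile"].iloc[140] == 2  # rank 141
        assert rp["percentile"].min() == 1 and rp["percentile"].max() == 100

    def test_matches_brute_force_sort(self):
        p = pd.Series({"A": 0.001, "B": 0.01, "C": 0.0001})
        rp = osc.rank_and_percentile(p)
        assert rp["rank"].to_dict() == {"C": 1, "A": 2, "B": 3}

    def test_ties_broken_by_gene_id(self):
        p = pd.Series({"Z": 0.5, "A": 0.5, "M": 0.5})
        rp = osc.rank_and_percentile(p)
        assert rp["rank"].to_dict() == {"A": 1, "M": 2, "Z": 3}

    def test_empty_input_rejected(self):
        with pytest.raises(osc.StudyValidationError):
            osc.rank_and_percentile(pd.Series(dtype=float))

    @given(st.integers(1, 1000), st.integers(0, 2**31 - 1))
    def test_random_vectors_match_argsort_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        p = pd.Series(rng.random(n), index=[f"g{i:04d}" for i in range(n)])
        rp = osc.rank_and_percentile(p)
        order = np.argsort(p.to_numpy(), kind="stable")
        expected_rank = np.empty(n, dtype=int)
        expected_rank[order] = np.arange(1, n + 1)
        assert (rp["rank"].to_numpy() == expected_rank).all()
        assert (rp["percentile"].to_numpy() == np.ceil(100 * expected_rank / n)).all()


class TestFdrQ:
    def test_direct_substitution(self):
        assert osc.fdr_q(1e-4, 10000, 5) == pytest.approx(0.2)

    def test_rank_equals_n_gives_p(self):
        assert osc.fdr_q(0.37, 250, 250) == pytest.approx(0.37)

    def test_rank_out_of_range_rejected(self):
        with pytest.raises(osc.StudyValidationError):
            osc.fdr_q(0.1, 10, 11)

    def test_monotone_mode_matches_step_up_oracle(self):
        p = np.array([0.001, 0.002, 0.9, 0.91])
        ranks = np.arange(1, 5)
        q = osc.fdr_q(p, 4, ranks, monotone=True)

        # independent step-up implementation
        raw = np.minimum(1.0, 4 * p / ranks)
        expected = np.minimum.accumulate(raw[::-1])[::-1]
        assert q == pytest.approx(expected)
        assert (np.diff(q) >= 0).all()

    def test_monotone_equals_benjamini_hochberg(self):
        # with ranks 1..N on sorted p, monotone Q is exactly the BH q-value
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = np.sort(rng.random(200))
        q = osc.fdr_q(p, len(p), np.arange(1, len(p) + 1), monotone=True)
        _, bh, _, _ = multipletests(p, method="fdr_bh")
        assert q == pytest.approx(bh)

    @given(st.integers(1, 500), st.integers(0, 2**31 - 1))
    def test_q_never_below_p(self, n, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(n)
        ranks = rng.permutation(n) + 1
        q = osc.fdr_q(p, n, ranks)
        assert (q >= p - 1e-12).all()


class TestAnalyzeStudy:
    def test_planted_gene_ranks_first(self, toy_study):
        res = osc.analyze_study(toy_study).set_index("gene")
        assert res.loc["GENE_B", "rank"] == 1
        assert res.loc["GENE_B", "direction"] == "over"
        assert res.loc["GENE_B", "fold_change"] == pytest.approx(87.5 / 10.5, rel=1e-6)
        assert (res["q"] >= res["p"] - 1e-12).all()
        assert (res["n_genes"] == 3).all()

    def test_all_identical_groups_pass_nothing(self):
        values = pd.DataFrame(
            np.tile([[4.0], [8.0]], (1, 4)), index=["g1", "g2"],
            columns=["c1", "c2", "n1", "n2"],
        )
        study = osc.ExpressionStudy(
            study_id="flat", cancer_type="x", cancer_subtype="y",
            values=values,
            groups=pd.Series(["cancer", "cancer", "normal", "normal"],
                             index=values.columns),
        )
        res = osc.analyze_study(study)
        assert (res["p"] == 1.0).all()
        assert (res["fold_change"] == 1.0).all()
        assert len(osc.filter_above_threshold(
            osc.attach_study_metadata(res, [study]))) == 0

    def test_row_order_invariance(self, toy_study):
        shuffled = osc.ExpressionStudy(
            study_id="toy", cancer_type="Brain", cancer_subtype="Glioblastoma",
            values=toy_study.values.iloc[::-1], groups=toy_study.groups,
        )
        pd.testing.assert_frame_equal(
            osc.analyze_study(toy_study), osc.analyze_study(shuffled)
        )

    def test_within_group_column_permutation_invariance(self, toy_study):
        perm = toy_study.values[["c2", "c1", "n2", "n1"]]
        study = osc.ExpressionStudy(
            study_id="toy", cancer_type="Brain", cancer_subtype="Glioblastoma",
            values=perm, groups=toy_study.groups.loc[perm.columns],
        )
        pd.testing.assert_frame_equal(
            osc.analyze_study(toy_study), osc.analyze_study(study)
        )

    def test_gene_with_missing_group_excluded_from_n(self, toy_study):
        values = toy_study.values.copy()
        values.loc["GENE_C", ["c1", "c2"]] = np.nan  # <2 cancer values left
        study = osc.ExpressionStudy(
            study_id="toy", cancer_type="Brain", cancer_subtype="Glioblastoma",
            values=values, groups=toy_study.groups,
        )
        res = osc.analyze_study(study)
        assert set(res["gene"]) == {"GENE_A", "GENE_B"}
        assert (res["n_genes"] == 2).all()

    def test_welch_flag_changes_statistic(self):
        rng = np.random.default_rng(5)
        values = pd.DataFrame(
            rng.lognormal(3, 0.7, size=(20, 10)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(10)],
        )
        groups = pd.Series(["cancer"] * 4 + ["normal"] * 6, index=values.columns)
        study = osc.ExpressionStudy(
            study_id="w", cancer_type="x", cancer_subtype="y",
            values=values, groups=groups,
        )
        pooled = osc.analyze_study(study, welch=False)
        welch = osc.analyze_study(study, welch=True)
        assert not np.allclose(pooled["p"], welch["p"])
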