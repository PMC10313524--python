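"""Association statistics: regression, t-test, ranks, BH, GSEA, clustering."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from idhtrial.associations import (
    DegenerateInputError,
    GeneStats,
    bh_adjust,
    per_gene_association,
    preranked_gsea,
    rank_statistic,
    simple_linear_regression,
    top_split_clusters,
    two_group_ttest,
)


class TestSimpleLinearRegression:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = simple_linear_regression(x, 2 * x)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_y(self):
        fit = simple_linear_regression([0, 1, 2, 3], [5, 5, 5, 5])
        assert fit.slope == 0.0 and fit.pvalue == 1.0

    def test_constant_x_rejected(self):
        with pytest.raises(DegenerateInputError):
            simple_linear_regression([1, 1, 1], [1, 2, 3])

    def test_six_point_worked_set_matches_normal_equations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.1, 2.9, 4.2, 4.8, 6.1, 6.9])
        fit = simple_linear_regression(x, y)
        # independent path: normal equations via lstsq + t reference
        design = np.column_stack([np.ones_like(x), x])
        (b0, b1), rss_arr = np.linalg.lstsq(design, y, rcond=None)[:2]
        rss = float(rss_arr[0])
        se = math.sqrt(rss / 4 / ((x - x.mean()) ** 2).sum())
        p = 2 * stats.t.sf(abs(b1 / se), 4)
        assert fit.slope == pytest.approx(b1, abs=1e-10)
        assert fit.intercept == pytest.approx(b0, abs=1e-10)
        assert fit.stderr == pytest.approx(se, abs=1e-10)
        assert fit.pvalue == pytest.approx(p, abs=1e-10)

    def test_matches_scipy_linregress(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(size=20)
        fit = simple_linear_regression(x, y)
        ref = stats.linregress(x, y)
        assert fit.slope == pytest.approx(ref.slope, abs=1e-12)
        assert fit.pvalue == pytest.approx(ref.pvalue, abs=1e-12)
        assert fit.r2 == pytest.approx(ref.rvalue**2, abs=1e-12)


class TestTwoGroupTtest:
    def test_identical_groups(self):
        assert two_group_ttest([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_shift_invariance(self):
        a, b = [1.0, 2.0, 4.0], [2.0, 5.0, 6.0, 7.0]
        t1, p1 = two_group_ttest(a, b)
        t2, p2 = two_group_ttest([v + 10 for v in a], [v + 10 for v in b])
        assert t1 == pytest.approx(t2) and p1 == pytest.approx(p2)

    def test_worked_values_match_pooled_formula(self):
        a = [4.2, 4.8, 5.1, 4.6, 5.0]
        b = [5.6, 6.1, 5.9, 6.4, 6.0]
        t, p = two_group_ttest(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_cases(self):
        assert two_group_ttest([1.0, 1.0], [1.0, 1.0]) == (0.0, 1.0)
        t, p = two_group_ttest([2.0, 2.0], [1.0, 1.0])
        assert p == 0.0 and t == math.inf


class TestRankStatistic:
    @pytest.mark.parametrize(
        "p,fc,expected", [(0.01, 1.5, 2.0), (0.001, -0.2, -3.0), (1.0, 5.0, 0.0),
                          (0.5, 0.0, 0.0)]
    )
    def test_values(self, p, fc, expected):
        assert rank_statistic(p, fc) == pytest.approx(expected)

    def test_p_zero_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            value = rank_statistic(0.0, 1.0)
        assert np.isfinite(value) and value > 300

    @given(p=st.floats(min_value=1e-10, max_value=1.0),
           fc=st.floats(min_value=-10, max_value=10))
    def test_antisymmetric_in_coefficient_sign(self, p, fc):
        assert rank_statistic(p, -fc) == pytest.approx(-rank_statistic(p, fc))


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_stepup_hand_computation(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(size=100)
        np.testing.assert_allclose(bh_adjust(p),
                                   multipletests(p, method="fdr_bh")[1],
                                   atol=1e-12)

    def test_pointwise_dominates_input_and_preserves_order(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert np.all(adj <= 1.0)


class TestPerGeneAssociation:
    def test_null_p_values_approximately_uniform(self):
        rng = np.random.default_rng(3)
        matrix = 2.0 ** rng.normal(5, 1, size=(2000, 30))
        covariate = rng.normal(size=30)
        result = per_gene_association(matrix, covariate)
        pvals = [g.pvalue for g in result]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
        assert np.mean(np.array(pvals) < 0.05) == pytest.approx(0.05, abs=0.02)

    def test_adjusted_dominate_raw(self):
        rng = np.random.default_rng(4)
        matrix = 2.0 ** rng.normal(5, 1, size=(200, 20))
        result = per_gene_association(matrix, rng.normal(size=20))
        assert all(g.adj_pvalue >= g.pvalue - 1e-12 for g in result)

    def test_zero_variance_gene_reports_null(self):
        rng = np.random.default_rng(5)
        matrix = 2.0 ** rng.normal(5, 1, size=(10, 15))
        matrix[3] = 8.0
        result = per_gene_association(matrix, rng.normal(size=15))
        assert result[3].pvalue == 1.0 and result[3].log2_fc == 0.0
        assert result[3].rank_score == 0.0

    def test_joint_permutation_invariance(self):
        rng = np.random.default_rng(6)
        matrix = 2.0 ** rng.normal(5, 1, size=(50, 12))
        covariate = rng.normal(size=12)
        perm = rng.permutation(12)
        a = per_gene_association(matrix, covariate)
        b = per_gene_association(matrix[:, perm], covariate[perm])
        for ga, gb in zip(a, b):
            assert ga.pvalue == pytest.approx(gb.pvalue, rel=1e-9)
            assert ga.log2_fc == pytest.approx(gb.log2_fc, rel=1e-9)


def _brute_force_es(scores_desc, member_mask, weight=1.0):
    """Independent running-sum computation, position by position."""
    n = len(scores_desc)
    n_set = sum(member_mask)
    nr = sum(abs(s) ** weight for s, m in zip(scores_desc, member_mask) if m)
    running, best = 0.0, 0.0
    for s, m in zip(scores_desc, member_mask):
        running += (abs(s) ** weight) / nr if m else -1.0 / (n - n_set)
        if abs(running) > abs(best):
            best = running
    return best


def _gene_stats_from_scores(scores):
    out = []
    for i, s in enumerate(scores):
        p = 10.0 ** (-abs(s)) if s != 0 else 1.0
        out.append(GeneStats(f"G{i:03d}", math.copysign(1.0, s) if s else 0.0,
                             p, p, s))
    return out


class TestPrerankedGsea:
    def test_es_matches_brute_force_oracle_on_toy_list(self):
        rng = np.random.default_rng(7)
        scores = np.round(rng.normal(size=20), 3)
        ranked = _gene_stats_from_scores(scores)
        ordered = sorted(ranked, key=lambda g: g.rank_score, reverse=True)
        members = {"G003", "G007", "G011", "G015", "G019"}
        mask = [g.gene_id in members for g in ordered]
        expected = _brute_force_es([g.rank_score for g in ordered], mask)
        (result,) = preranked_gsea(ranked, {"TOY": sorted(members)},
                                   n_perm=10, min_size=1, max_size=500, seed=0)
        assert result.es == pytest.approx(expected, abs=1e-12)

    def test_top_k_set_has_large_positive_es(self):
        scores = np.linspace(3, -3, 100)
        ranked = _gene_stats_from_scores(scores)
        top = [g.gene_id for g in sorted(ranked, key=lambda g: g.rank_score,
                                         reverse=True)[:15]]
        (result,) = preranked_gsea(ranked, {"TOP": top}, n_perm=50, seed=1)
        assert result.es > 0.9
        assert result.pvalue < 0.05

    def test_small_set_dropped_under_default_bounds(self):
        ranked = _gene_stats_from_scores(np.linspace(2, -2, 50))
        results = preranked_gsea(ranked, {"TINY": [g.gene_id for g in ranked[:5]]},
                                 n_perm=10, seed=2)
        assert results == []

    def test_es_sign_flips_under_score_negation(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=40)
        members = [f"G{i:03d}" for i in (1, 5, 9, 13, 17)]
        kw = dict(n_perm=20, min_size=1, max_size=500, seed=3)
        (pos,) = preranked_gsea(_gene_stats_from_scores(scores),
                                {"S": members}, **kw)
        (neg,) = preranked_gsea(_gene_stats_from_scores(-scores),
                                {"S": members}, **kw)
        assert neg.es == pytest.approx(-pos.es, abs=1e-12)

    def test_permutation_p_is_seed_deterministic(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=60)
        members = [f"G{i:03d}" for i in range(0, 60, 3)]
        kw = dict(n_perm=100, min_size=1, max_size=500, seed=4)
        (a,) = preranked_gsea(_gene_stats_from_scores(scores), {"S": members}, **kw)
        (b,) = preranked_gsea(_gene_stats_from_scores(scores), {"S": members}, **kw)
        assert a == b

    def test_disjoint_set_skipped_with_warning(self):
        ranked = _gene_stats_from_scores(np.linspace(1, -1, 30))
        with pytest.warns(UserWarning, match="no overlap"):
            results = preranked_gsea(ranked, {"ALIEN": ["X1", "X2"]}, n_perm=10,
                                     min_size=1, seed=5)
        assert results == []


class TestTopSplitClusters:
    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(10)
        left = rng.normal(0, 1, size=(30, 8))
        right = rng.normal(6, 1, size=(30, 7))
        matrix = np.hstack([left, right])
        external = np.r_[np.zeros(8), np.ones(7)]
        labels, (t, p) = top_split_clusters(matrix, external)
        # perfect blob recovery up to label swap
        assert len(set(labels[:8])) == 1 and len(set(labels[8:])) == 1
        assert labels[0] != labels[-1]
        assert p < 1e-6

    def test_signature_matrix_separates_by_2hg(self):
        from idhtrial.simulate import ExpressionSpec, GeneratorConfig, \
            simulate_expression

        config = GeneratorConfig(expression=ExpressionSpec(
            n_genes=60, n_signature_genes=40, effect=2.0, noise_sd=0.4))
        rng = np.random.default_rng(11)
        covariate = np.r_[rng.normal(0.8, 0.2, 15), rng.normal(2.3, 0.2, 15)]
        matrix, _, signature = simulate_expression(config, covariate, seed=11)
        labels, (t, p) = top_split_clusters(np.log2(matrix[:len(signature)]),
                                            covariate)
        assert p < 0.05

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            top_split_clusters(np.ones((5, 1)), [1.0])

    def test_identical_samples_rejected(self):
        with pytest.raises(DegenerateInputError):
            top_split_clusters(np.tile([[1.0], [2.0]], (1, 4)), [1, 2, 3, 4])
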