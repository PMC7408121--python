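import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import omicspair as op
from conftest import naive_ols


def phenotype(n0, n1):
    return np.array([0.0] * n0 + [1.0] * n1)


class TestFitPair:
    def test_null_construction_beta4_zero(self, rng):
        p = phenotype(6, 6)
        g = rng.normal(size=12)
        m = 1.0 + 2.0 * g + 0.5 * p
        res = op.fit_pair(g, m, p)
        # exact linear construction: the interaction coefficient vanishes
        # (its p-value is a 0/0 artifact at machine precision, not asserted)
        assert abs(res.beta4) < 1e-10

    def test_perfect_interaction(self, rng):
        p = phenotype(6, 6)
        g = rng.normal(size=12)
        m = g * p
        res = op.fit_pair(g, m, p)
        np.testing.assert_allclose(res.beta4, 1.0, atol=1e-10)
        # exact fit: p collapses toward the underflow floor (machine-precision
        # residuals keep it from reaching it exactly)
        assert res.p_interaction < 1e-80

    def test_matches_naive_normal_equations(self, rng):
        p = phenotype(8, 12)
        for _ in range(30):
            g = rng.normal(size=20)
            m = rng.normal(size=20)
            res = op.fit_pair(g, m, p)
            X = np.column_stack([np.ones(20), g, p, g * p])
            beta, se, dof = naive_ols(X, m)
            np.testing.assert_allclose(
                [res.beta1, res.beta2, res.beta3, res.beta4], beta, atol=1e-10)
            np.testing.assert_allclose(res.se_beta4, se[3], atol=1e-10)
            expected_p = 2 * stats.t.sf(abs(beta[3] / se[3]), dof)
            np.testing.assert_allclose(res.p_interaction, expected_p, rtol=1e-8)

    def test_constant_gene_flagged_not_crash(self):
        p = phenotype(5, 5)
        res = op.fit_pair(np.ones(10), np.arange(10.0), p)
        assert res.singular
        assert res.p_interaction == 1.0

    def test_too_few_samples(self):
        with pytest.raises(op.UsageError):
            op.fit_pair(np.ones(5), np.ones(5), np.array([0, 0, 0, 1, 1.0]))

    def test_group_minimum(self):
        with pytest.raises(op.UsageError):
            op.fit_pair(np.arange(8.0), np.arange(8.0), np.array([0, 0, 0, 0, 0, 0, 1, 1.0]))


class TestSpearman:
    def test_identity_both_groups(self, rng):
        p = phenotype(5, 5)
        g = rng.normal(size=10)
        assert op.spearman_by_group(g, g, p) == (1.0, 1.0)

    def test_opposite_signs(self, rng):
        p = phenotype(5, 5)
        g = rng.normal(size=10)
        m = np.where(p == 0, -g, g)
        c0, c1 = op.spearman_by_group(g, m, p)
        np.testing.assert_allclose([c0, c1], [-1.0, 1.0], atol=1e-12)

    def test_matches_rank_then_pearson_oracle(self, rng):
        p = phenotype(10, 10)
        for _ in range(20):
            g = rng.normal(size=20)
            m = rng.normal(size=20)
            c0, c1 = op.spearman_by_group(g, m, p)
            for level, got in ((0, c0), (1, c1)):
                mask = p == level
                rg = stats.rankdata(g[mask])
                rm = stats.rankdata(m[mask])
                expected = np.corrcoef(rg, rm)[0, 1]
                np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_ties_average_ranks(self):
        p = phenotype(4, 4)
        g = np.array([1.0, 1.0, 2.0, 3.0, 1.0, 2.0, 2.0, 3.0])
        m = np.array([2.0, 2.0, 3.0, 4.0, 5.0, 5.0, 6.0, 7.0])
        c0, c1 = op.spearman_by_group(g, m, p)
        r0 = stats.spearmanr(g[:4], m[:4]).statistic
        r1 = stats.spearmanr(g[4:], m[4:]).statistic
        np.testing.assert_allclose([c0, c1], [r0, r1], atol=1e-12)

    def test_constant_vector_reports_zero(self):
        p = phenotype(3, 3)
        c0, c1 = op.spearman_by_group(np.array([1, 1, 1, 1, 2, 3.0]),
                                      np.arange(6.0), p)
        assert c0 == 0.0

    @given(a=st.floats(0.1, 5.0), b=st.floats(-10.0, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_monotone_transform_invariance(self, a, b):
        rng = np.random.default_rng(5)
        p = phenotype(6, 6)
        g = rng.normal(size=12)
        m = rng.normal(size=12)
        base = op.spearman_by_group(g, m, p)
        trans = op.spearman_by_group(a * g + b, np.exp(a * m), p)
        np.testing.assert_allclose(base, trans, atol=1e-12)


class TestCorrelationDifference:
    def test_printed_breed_example(self):
        # group0 = Duroc, group1 = Landrace
        assert round(op.correlation_difference(0.776224, -0.54242), 5) == -1.31864

    def test_printed_fe_example(self):
        # group0 = high FE, group1 = low FE
        assert round(op.correlation_difference(0.66996, -0.73284), 4) == -1.4028

    def test_equal_correlations_zero(self):
        assert op.correlation_difference(0.3, 0.3) == 0.0


class TestBhFdr:
    def test_single_p_identity(self):
        np.testing.assert_allclose(op.bh_fdr([0.03]), [0.03])

    def test_hand_evaluated_step_up(self):
        np.testing.assert_allclose(op.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_order_preserved(self):
        adj = op.bh_fdr([0.04, 0.01, 0.5])
        assert adj[1] < adj[0] <= adj[2]

    def test_against_statsmodels_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(1000):
            p = rng.uniform(1e-12, 1.0, size=rng.integers(1, 30))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(op.bh_fdr(p), expected, atol=1e-12)

    def test_against_definitional_oracle(self, rng):
        # min over j with p_j >= p_i of m*p_j/rank_j, capped at 1
        for _ in range(50):
            p = rng.uniform(0, 1, size=20)
            m = len(p)
            ranks = {v: r for r, v in enumerate(sorted(p), start=1)}
            expected = [min(min(m * q / ranks[q] for q in p if q >= v), 1.0) for v in p]
            np.testing.assert_allclose(op.bh_fdr(p), expected, atol=1e-12)

    def test_invalid_values_rejected(self):
        with pytest.raises(op.UsageError):
            op.bh_fdr([0.0, 0.5])
        with pytest.raises(op.UsageError):
            op.bh_fdr([1.5])

    @given(st.lists(st.floats(1e-10, 1.0), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_at_least_raw_over_m(self, pvals):
        p = np.asarray(pvals)
        adj = op.bh_fdr(p)
        assert np.all(adj >= p / len(p) - 1e-15)
        assert np.all(adj <= 1.0)


class TestRunAllPairs:
    def test_model_count_trivial(self, random_pair_instance):
        genes, mets, p = random_pair_instance
        g2 = genes.select_features(genes.feature_ids[:2])
        m3 = mets.select_features(mets.feature_ids[:3])
        results, count = op.run_all_pairs(g2, m3, p)
        assert count == 6
        assert len(results) == 6

    @pytest.mark.parametrize("n_genes,n_mets,expected",
                             [(16839, 405, 6819795), (16812, 405, 6808860)])
    def test_model_count_full_scale_stub(self, n_genes, n_mets, expected, rng):
        genes = op.OmicsMatrix([f"g{i}" for i in range(n_genes)],
                               [f"s{j}" for j in range(8)],
                               rng.normal(size=(n_genes, 8)), "adjusted")
        mets = op.OmicsMatrix([f"m{i}" for i in range(n_mets)],
                              [f"s{j}" for j in range(8)],
                              rng.normal(size=(n_mets, 8)), "adjusted")
        p = np.array([0, 0, 0, 0, 1, 1, 1, 1.0])
        _, count = op.run_all_pairs(genes, mets, p, count_only=True)
        assert count == expected

    def test_equals_per_pair_oracle(self, random_pair_instance):
        genes, mets, p = random_pair_instance
        results, count = op.run_all_pairs(genes, mets, p, block_size=7)
        assert count == 50 * 20
        idx = {(r.gene_id, r.metabolite_id): r for r in results.itertuples()}
        for gi, gid in enumerate(genes.feature_ids):
            for mi, mid in enumerate(mets.feature_ids):
                single = op.fit_pair(genes.values[gi], mets.values[mi], p, gid, mid)
                row = idx[(gid, mid)]
                np.testing.assert_allclose(
                    [row.beta1, row.beta2, row.beta3, row.beta4, row.se_beta4,
                     row.cor_group0, row.cor_group1],
                    [single.beta1, single.beta2, single.beta3, single.beta4,
                     single.se_beta4, single.cor_group0, single.cor_group1],
                    atol=1e-10)
                np.testing.assert_allclose(row.p_interaction, single.p_interaction,
                                           rtol=1e-8, atol=1e-12)

    def test_block_size_invariance(self, random_pair_instance):
        genes, mets, p = random_pair_instance
        r1, _ = op.run_all_pairs(genes, mets, p, block_size=3)
        r2, _ = op.run_all_pairs(genes, mets, p, block_size=1000)
        pd.testing.assert_frame_equal(r1, r2)

    def test_sample_mismatch_lists_offenders(self, random_pair_instance):
        genes, mets, p = random_pair_instance
        bad = op.OmicsMatrix(mets.feature_ids, ["x" + s for s in mets.sample_ids],
                             mets.values, "adjusted")
        with pytest.raises(op.UsageError, match="xs0"):
            op.run_all_pairs(genes, bad, p)

    def test_swapping_levels_negates_diff_and_keeps_p(self, random_pair_instance):
        genes, mets, p = random_pair_instance
        r1, _ = op.run_all_pairs(genes, mets, p)
        r2, _ = op.run_all_pairs(genes, mets, 1.0 - p)
        np.testing.assert_allclose(r1["diff_corr"], -r2["diff_corr"], atol=1e-12)
        np.testing.assert_allclose(r1["p_interaction"], r2["p_interaction"],
                                   rtol=1e-9, atol=1e-12)

    def test_fdr_computed_across_all_pairs(self, random_pair_instance):
        genes, mets, p = random_pair_instance
        results, _ = op.run_all_pairs(genes, mets, p)
        np.testing.assert_allclose(results["fdr"],
                                   op.bh_fdr(results["p_interaction"].to_numpy()),
                                   atol=1e-12)


class TestFilterSignificant:
    def test_thresholds(self):
        frame = pd.DataFrame({
            "p_interaction": [1e-8, 1e-8, 1e-8, 1e-3],
            "fdr": [0.05, 0.05, 0.2, 0.05],
            "diff_corr": [0.5, 0.05, 0.5, -0.5],
        })
        out = op.filter_significant(frame)
        assert list(out.index) == [0, 3]
        assert out["significant"].all()

    def test_raw_p_screen(self):
        frame = pd.DataFrame({
            "p_interaction": [1e-8, 1e-6],
            "fdr": [0.05, 0.05],
            "diff_corr": [0.5, 0.5],
        })
        out = op.filter_significant(frame, raw_p_max=1e-7)
        assert list(out.index) == [0]

    def test_empty_input(self):
        frame = pd.DataFrame(columns=["p_interaction", "fdr", "diff_corr"])
        assert len(op.filter_significant(frame)) == 0


class TestPhenotypeCoding:
    def test_encode(self, meta_table):
        coding = op.PhenotypeCoding("breed", "a", "b")
        p = coding.encode(meta_table, meta_table.sample_ids)
        assert p.tolist() == [0.0] * 12 + [1.0] * 12

    def test_unexpected_level_errors(self, meta_table):
        coding = op.PhenotypeCoding("breed", "a", "z")
        with pytest.raises(op.UsageError, match="unexpected"):
            coding.encode(meta_table, meta_table.sample_ids)

    def test_swapped(self):
        coding = op.PhenotypeCoding("breed", "a", "b").swapped()
        assert (coding.level0, coding.level1) == ("b", "a")
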