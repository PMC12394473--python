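"""Tests for HTQ scoring, responder rule, and the univariate statistics."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from gonogo.clinical import (DEFAULT_SUBSCALES, adjust_pvalues,
                             baseline_change_regression, bonferroni_threshold,
                             chi_square_yates, classify_responder, cliffs_delta,
                             cohens_d, fisher_exact, mann_whitney_u, score_htq,
                             sensitivity_model, wilcoxon_signed_rank)
from gonogo.clinical import _cliffs_delta_brute, _cliffs_delta_ranked


def record(items, sid="s1", tp="pre"):
    return score_htq(np.asarray(items), subject_id=sid, timepoint=tp)


class TestHTQScoring:
    @pytest.mark.parametrize("fill,total", [(1, 1.0), (4, 4.0)])
    def test_constant_items(self, fill, total):
        assert record([fill] * 16).total == total

    def test_halfway_total_hits_cutoff(self):
        rec = record([2] * 8 + [3] * 8)
        assert rec.total == 2.5 and rec.above_cutoff

    def test_subscales_cover_all_items(self):
        covered = sorted(i for idx in DEFAULT_SUBSCALES.values() for i in idx)
        assert covered == list(range(1, 17))
        rec = record(list(range(1, 5)) * 4)
        assert set(rec.subscales) == set(DEFAULT_SUBSCALES)

    @pytest.mark.parametrize("bad", [[0] * 16, [5] * 16, [1] * 15, [1.5] * 16])
    def test_invalid_items_rejected(self, bad):
        with pytest.raises(ValueError):
            score_htq(np.asarray(bad))


class TestResponderRule:
    def test_boundary_decrease_of_half_point(self):
        # totals 3.0 -> 2.5: decrease exactly 0.5 on the 1/16 grid
        pre = record([3] * 16, tp="pre")
        post = record([3] * 8 + [2] * 8, tp="post")
        assert pre.total - post.total == pytest.approx(0.5)
        assert classify_responder(pre, post) == "responder"

    def test_no_change_and_worsening(self):
        pre = record([3] * 16, tp="pre")
        assert classify_responder(pre, record([3] * 16, tp="post")) == "non_responder"
        assert classify_responder(pre, record([4] * 16, tp="post")) == "non_responder"

    def test_subject_and_timepoint_checks(self):
        pre = record([3] * 16, "a", "pre")
        with pytest.raises(ValueError):
            classify_responder(pre, record([2] * 16, "b", "post"))
        with pytest.raises(ValueError):
            classify_responder(pre, record([2] * 16, "a", "pre"))


class TestMannWhitney:
    def test_full_separation(self):
        u, _ = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_identical_groups_near_one(self):
        _, p = mann_whitney_u([1, 2, 3, 4, 5], [1.1, 2.1, 2.9, 4.2, 4.8])
        assert p > 0.5

    def test_matches_enumeration_oracle_n6(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(6), rng.standard_normal(6)
        _, p = mann_whitney_u(a, b)
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        u_obs = ranks[:6].sum() - 21
        count = total = 0
        for comb_idx in combinations(range(12), 6):
            u = ranks[list(comb_idx)].sum() - 21
            count += abs(u - 18) >= abs(u_obs - 18) - 1e-12
            total += 1
        assert p == pytest.approx(count / total, abs=1e-9)


class TestWilcoxonScalar:
    def test_rank_sums_partition(self):
        rng = np.random.default_rng(1)
        pre, post = rng.standard_normal(12), rng.standard_normal(12)
        w_plus, w_minus, z, p = wilcoxon_signed_rank(pre, post)
        assert w_plus + w_minus == pytest.approx(12 * 13 / 2)
        assert 0 < p <= 1

    def test_all_equal_flagged(self):
        w_plus, w_minus, z, p = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert z == 0.0 and p == 1.0

    def test_matches_scipy_statistic(self):
        rng = np.random.default_rng(2)
        pre, post = rng.standard_normal(15), rng.standard_normal(15)
        w_plus, w_minus, _, _ = wilcoxon_signed_rank(pre, post)
        assert min(w_plus, w_minus) == stats.wilcoxon(pre - post).statistic


class TestContingency:
    def test_yates_flooring_at_equal_counts(self):
        chi2, p = chi_square_yates([[10, 10], [10, 10]])
        assert chi2 == 0.0 and p == 1.0

    def test_matches_scipy_when_flooring_inactive(self):
        chi2, p = chi_square_yates([[18, 4], [13, 12]])
        s_chi2, s_p, _, _ = stats.chi2_contingency([[18, 4], [13, 12]],
                                                   correction=True)
        assert chi2 == pytest.approx(s_chi2)
        assert p == pytest.approx(s_p)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_yates([[0, 0], [5, 5]])
        with pytest.raises(ValueError):
            fisher_exact([[0, 5], [0, 5]])

    def test_fisher_hypergeometric_value(self):
        assert fisher_exact([[5, 0], [0, 5]]) == pytest.approx(2 / 252, abs=1e-9)

    def test_fisher_symmetries(self):
        assert fisher_exact([[1, 1], [1, 1]]) == 1.0
        t = [[7, 3], [2, 9]]
        assert fisher_exact(t) == pytest.approx(fisher_exact(np.transpose(t)))


class TestCohensD:
    def test_identical_distributions_zero(self):
        d, _ = cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0

    def test_one_pooled_sd_shift(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        d, ci = cohens_d(a + a.std(ddof=1), a)
        assert d == pytest.approx(1.0)
        assert ci[0] < 1.0 < ci[1]

    def test_zero_variance_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            cohens_d([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])

    def test_paired_recovery_simulation(self):
        rng = np.random.default_rng(3)
        true_d, n, reps = 1.3, 47, 300
        ests = []
        for _ in range(reps):
            diff = rng.normal(true_d, 1.0, size=n)
            d, _ = cohens_d(diff + 5.0, np.full(n, 5.0), design="paired")
            ests.append(d)
        se = np.sqrt(1 / n + true_d ** 2 / (2 * n))
        assert abs(np.mean(ests) - true_d) < 3 * se / np.sqrt(reps) + 0.03


class TestCliffsDelta:
    def test_identical_constant_samples(self):
        assert cliffs_delta([2.0, 2.0], [2.0, 2.0])[0] == 0.0

    def test_full_separation(self):
        delta, _ = cliffs_delta([10.0, 11.0], [1.0, 2.0])
        assert delta == 1.0

    def test_antisymmetry_and_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a, b = rng.standard_normal(15), rng.standard_normal(20)
            d_ab, _ = cliffs_delta(a, b)
            d_ba, _ = cliffs_delta(b, a)
            assert d_ab == -d_ba
            assert -1.0 <= d_ab <= 1.0

    def test_both_paths_agree_exactly(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = rng.integers(0, 10, size=rng.integers(2, 40)).astype(float)
            b = rng.integers(0, 10, size=rng.integers(2, 40)).astype(float)
            assert _cliffs_delta_brute(a, b) == pytest.approx(
                _cliffs_delta_ranked(a, b), abs=1e-12)


class TestMultiplicity:
    def test_printed_thresholds(self):
        assert round(bonferroni_threshold(0.05, 6), 4) == 0.0083
        assert bonferroni_threshold(0.05, 8) == 0.00625

    def test_bh_stepup_hand_computation(self):
        adj = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "fdr_bh")
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_bonferroni_and_bh_agree_at_m1(self):
        p = [0.037]
        assert adjust_pvalues(p, "bonferroni")[0] == adjust_pvalues(p, "fdr_bh")[0]

    def test_m_larger_than_list(self):
        assert adjust_pvalues([0.01], "bonferroni", m=5)[0] == pytest.approx(0.05)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.0, 0.5])


class TestRegressions:
    def test_zero_change_degenerate(self):
        slope, intercept, r2, f, p = baseline_change_regression(
            [2.0, 3.0, 4.0], [0.0, 0.0, 0.0])
        assert slope == 0.0 and r2 == 0.0

    def test_perfect_negative_coupling(self):
        pre = np.array([2.0, 2.5, 3.0, 3.5, 4.0])
        slope, intercept, r2, _, _ = baseline_change_regression(pre, -pre + 1.0)
        assert slope == pytest.approx(-1.0)
        assert r2 == pytest.approx(1.0)

    def test_severity_coupled_generator_gives_negative_slope(self):
        from gonogo.synth import CohortConfig, generate_htq_cohort
        cohort = generate_htq_cohort(CohortConfig(n_controls=0, seed=11))
        item_cols = [f"item_{j:02d}" for j in range(1, 17)]
        pre = cohort.htq[cohort.htq.timepoint == "pre"].set_index("subject_id")
        post = cohort.htq[cohort.htq.timepoint == "post"].set_index("subject_id")
        sids = cohort.metadata.subject_id
        pre_t = pre.loc[sids, item_cols].astype(float).mean(axis=1)
        post_t = post.loc[sids, item_cols].astype(float).mean(axis=1)
        slope, *_ = baseline_change_regression(pre_t, post_t - pre_t)
        assert slope < 0  # responders (larger decreases) start more severe

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            baseline_change_regression([2.0, 2.0, 2.0], [0.1, 0.2, 0.3])

    def test_sensitivity_model_planted_responder_effect(self):
        rng = np.random.default_rng(6)
        resp = np.array([1] * 22 + [0] * 25)
        med = rng.integers(0, 2, size=47)
        change = resp * 1.0 + rng.normal(0, 0.35, 47)
        table = sensitivity_model(change, resp, med)
        row = table.set_index("predictor")
        assert row.loc["responder", "p"] < 0.001
        assert row.loc["responder", "df_den"] == 44.0

    def test_sensitivity_model_degenerate_inputs(self):
        resp = np.array([1, 1, 0, 0, 1, 0])
        with pytest.raises(ValueError, match="collinear"):
            sensitivity_model(np.arange(6.0), resp, resp)
        with pytest.raises(ValueError):
            sensitivity_model(np.zeros(6), resp, np.array([0, 1, 1, 0, 0, 1]))
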