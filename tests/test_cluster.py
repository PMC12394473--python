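"""Tests for the rank-based pointwise statistics and cluster permutation test."""

import numpy as np
import pytest
from scipy import stats

from gonogo.cluster import (Cluster, PointwiseStatMap, form_clusters,
                            permutation_test, rank_sum_z, wilcoxon_signed_rank_z)
from gonogo.synth import difference_effect, simulate_subject_waveforms


class TestSignedRankZ:
    def test_all_zero_differences(self):
        m = wilcoxon_signed_rank_z(np.zeros((8, 1, 1)))
        assert m.z[0, 0] == 0.0 and m.p[0, 0] == 1.0
        assert m.n_effective[0, 0] == 0

    def test_hand_formula_all_positive_n10(self):
        d = np.arange(1.0, 11.0)[:, None, None]
        m = wilcoxon_signed_rank_z(d)
        assert m.z[0, 0] == pytest.approx(27.5 / np.sqrt(96.25))

    def test_symmetric_differences_give_zero(self):
        d = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])[:, None, None]
        assert wilcoxon_signed_rank_z(d).z[0, 0] == pytest.approx(0.0)

    def test_sign_tracks_direction(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            d = rng.standard_normal(15) + rng.uniform(-1, 1)
            z = wilcoxon_signed_rank_z(d[:, None, None]).z[0, 0]
            signed_rank_sum = (stats.rankdata(np.abs(d)) * np.sign(d)).sum()
            if signed_rank_sum != 0:
                assert np.sign(z) == np.sign(signed_rank_sum)

    def test_zero_dropping_reduces_n(self):
        d = np.array([0.0, 0.0, 1.0, 2.0, 3.0, 4.0, 5.0])[:, None, None]
        m = wilcoxon_signed_rank_z(d)
        assert m.n_effective[0, 0] == 5
        assert m.z[0, 0] == pytest.approx(7.5 / np.sqrt(5 * 6 * 11 / 24))

    def test_p_tracks_exact_distribution(self):
        """Asymptotic p agrees with the exhaustive null in sign and rank order,
        and converges toward it as n grows (tie-free data)."""
        rng = np.random.default_rng(1)
        for n, tol in ((8, 0.13), (12, 0.05), (25, 0.02)):
            worst = 0.0
            for _ in range(100):
                d = rng.standard_normal(n)
                p_approx = wilcoxon_signed_rank_z(d[:, None, None]).p[0, 0]
                p_exact = stats.wilcoxon(d, method="exact").pvalue
                worst = max(worst, abs(p_approx - p_exact))
            assert worst <= tol


class TestRankSumZ:
    def test_identical_groups_zero(self):
        a = np.tile(np.arange(5.0), (1, 1, 1)).reshape(5, 1, 1)
        assert rank_sum_z(a, a.copy()).z[0, 0] == 0.0

    def test_full_separation_hand_formula(self):
        a = np.arange(11.0, 21.0)[:, None, None]
        b = np.arange(1.0, 11.0)[:, None, None]
        m = rank_sum_z(a, b)
        # U = 100, mu = 50, var = 100 * 21 / 12 = 175
        assert m.z[0, 0] == pytest.approx(50.0 / np.sqrt(175.0))

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((8, 2, 5))
        b = rng.standard_normal((10, 2, 5))
        assert np.allclose(rank_sum_z(a, b).z, -rank_sum_z(b, a).z)

    def test_tie_correction_matches_scipy(self):
        a = np.repeat([1.0, 2.0, 3.0], 5)[:, None, None]
        b = np.repeat([2.0, 3.0, 4.0], 5)[:, None, None]
        p_ours = rank_sum_z(a, b).p[0, 0]
        # scipy applies a continuity correction; agreement is approximate
        p_scipy = stats.mannwhitneyu(a[:, 0, 0], b[:, 0, 0],
                                     method="asymptotic").pvalue
        assert p_ours == pytest.approx(p_scipy, abs=0.002)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_z(np.empty((0, 1, 1)), np.ones((5, 1, 1)))


def _bruteforce_components(mask, adjacency):
    """Flood-fill oracle for cluster formation."""
    n_ch, n_t = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for c0 in range(n_ch):
        for t0 in range(n_t):
            if not mask[c0, t0] or seen[c0, t0]:
                continue
            stack, comp = [(c0, t0)], []
            seen[c0, t0] = True
            while stack:
                c, t = stack.pop()
                comp.append((c, t))
                for cc, tt in [(c, t - 1), (c, t + 1)] + \
                        [(c2, t) for c2 in range(n_ch) if adjacency[c, c2]]:
                    if 0 <= tt < n_t and mask[cc, tt] and not seen[cc, tt]:
                        seen[cc, tt] = True
                        stack.append((cc, tt))
            comps.append(sorted(comp))
    return sorted(comps)


class TestFormClusters:
    def _map(self, z):
        z = np.asarray(z, float)
        p = 2 * stats.norm.sf(np.abs(z))
        return PointwiseStatMap(z=z, p=p)

    def test_no_suprathreshold_points(self):
        assert form_clusters(self._map(np.zeros((2, 20)))) == []

    def test_subthreshold_gap_splits_clusters(self):
        z = np.zeros((1, 50))
        z[0, 10:21] = 3.0
        z[0, 30:41] = 3.0
        clusters = form_clusters(self._map(z))
        assert len(clusters) == 2
        assert all(c.mass == pytest.approx(33.0) for c in clusters)

    def test_adjacent_channels_merge_at_same_time(self):
        z = np.zeros((2, 30))
        z[0, 10:15] = 3.0
        z[1, 14:20] = 3.0  # overlaps channel 0 only at t=14
        merged = form_clusters(self._map(z))  # two channels -> adjacent
        assert len(merged) == 1
        separate = form_clusters(self._map(z), adjacency=np.zeros((2, 2), bool))
        assert len(separate) == 2

    def test_opposite_signs_never_merge(self):
        z = np.zeros((1, 20))
        z[0, 5:10] = 3.0
        z[0, 10:15] = -3.0
        clusters = form_clusters(self._map(z))
        assert len(clusters) == 2
        assert {c.sign for c in clusters} == {1, -1}

    def test_matches_bruteforce_flood_fill(self):
        rng = np.random.default_rng(5)
        adjacency = np.zeros((3, 3), dtype=bool)
        adjacency[0, 1] = adjacency[1, 0] = True
        adjacency[1, 2] = adjacency[2, 1] = True
        for _ in range(30):
            z = rng.standard_normal((3, 40)) * 2.0
            clusters = form_clusters(self._map(z), adjacency=adjacency)
            got = sorted(sorted(c.members) for c in clusters)
            mask = 2 * stats.norm.sf(np.abs(z)) < 0.05
            expected = []
            for sign in (1, -1):
                expected += _bruteforce_components(
                    mask & ((z > 0) if sign > 0 else (z < 0)), adjacency)
            assert got == sorted(expected)
            for c in clusters:
                assert c.mass == pytest.approx(
                    sum(z[ch, t] for ch, t in c.members))


class TestPermutationTest:
    def test_tiny_n_exhaustive_sign_flips(self):
        d = np.full((3, 2, 250), 0.0)
        d[:, :, 100:130] = 5.0
        res = permutation_test(d, design="paired", n_permutations=100, seed=0)
        assert res.exhaustive
        assert res.n_permutations == 8
        assert all(c.p_value >= 1 / 8 for c in res.clusters)

    def test_deterministic_under_seed(self):
        waves = simulate_subject_waveforms(12, difference_effect(2.0), 2.0, seed=4)
        r1 = permutation_test(waves, n_permutations=200, seed=9)
        r2 = permutation_test(waves, n_permutations=200, seed=9)
        assert np.array_equal(r1.max_null_distribution, r2.max_null_distribution)
        assert [c.p_value for c in r1.clusters] == [c.p_value for c in r2.clusters]

    def test_p_monotone_in_cluster_mass(self):
        waves = simulate_subject_waveforms(15, difference_effect(2.0), 2.5, seed=6)
        res = permutation_test(waves, n_permutations=300, seed=6)
        masses = [abs(c.mass) for c in res.clusters]
        ps = [c.p_value for c in res.clusters]
        assert masses == sorted(masses, reverse=True)
        assert ps == sorted(ps)

    def test_channel_order_invariance(self):
        waves = simulate_subject_waveforms(12, difference_effect(3.0), 2.0, seed=7)
        r1 = permutation_test(waves, n_permutations=200, seed=3)
        r2 = permutation_test(waves[:, ::-1, :], n_permutations=200, seed=3,
                              channel_names=("Cz", "Fz"))
        assert np.allclose(sorted(c.mass for c in r1.clusters),
                           sorted(c.mass for c in r2.clusters))
        assert [c.p_value for c in r1.clusters] \
            == [c.p_value for c in sorted(r2.clusters, key=lambda c: -abs(c.mass))]

    def test_observed_window_recovered(self):
        waves = simulate_subject_waveforms(20, difference_effect(3.0), 2.0, seed=8)
        res = permutation_test(waves, n_permutations=200, seed=8)
        top = res.clusters[0]
        assert top.sign > 0 and top.p_value < 0.05
        times = res.time_ms[top.time_indices]
        assert times.min() < 400 < times.max()

    def test_independent_design_exhaustive_small_groups(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal((4, 2, 250)) + difference_effect(4.0)
        b = rng.standard_normal((4, 2, 250))
        res = permutation_test((a, b), design="independent",
                               n_permutations=100, seed=0)
        assert res.exhaustive and res.n_permutations == 70
        assert all(c.p_value >= 1 / 70 for c in res.clusters)

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(np.zeros((5, 2, 250)), n_permutations=50)

    def test_quick_null_calibration(self):
        """No significant cluster in the clear majority of null datasets."""
        hits = 0
        for rep in range(40):
            waves = simulate_subject_waveforms(15, np.zeros((2, 250)), 2.0,
                                               seed=1000 + rep)
            res = permutation_test(waves, n_permutations=150, seed=rep)
            hits += bool(res.significant)
        assert hits <= 8  # ~5% expected; binomial slack at 40 replicates
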