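import numpy as np
import pytest

from plzcmeg.cluster_stats import (cbpt, cluster_mean_rho, cohens_d,
                                   form_clusters, source_correlation,
                                   source_ttest)
from plzcmeg.grid import make_grid

from oracles import connected_components


class TestSourceTtest:
    def test_identical_groups_give_zero_t(self):
        X = np.array([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]])
        t, p = source_ttest(X, ["F", "F", "F", "M", "M", "M"])
        assert t[0] == pytest.approx(0.0)
        assert p[0] == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        # {1,2,3} vs {2,3,4}: pooled variance 1, t = -1/sqrt(2/3)
        X = np.array([[1.0], [2.0], [3.0], [2.0], [3.0], [4.0]])
        t, p = source_ttest(X, ["F", "F", "F", "M", "M", "M"])
        assert t[0] == pytest.approx(-1.2247, abs=1e-4)
        assert p[0] == pytest.approx(0.2879, abs=1e-3)

    def test_within_group_permutation_invariance(self, rng):
        X = rng.standard_normal((8, 5))
        g = np.array(["F"] * 4 + ["M"] * 4)
        t1, _ = source_ttest(X, g)
        order = np.r_[rng.permutation(4), 4 + rng.permutation(4)]
        t2, _ = source_ttest(X[order], g)
        assert np.allclose(t1, t2)

    def test_zero_variance_source_flagged(self):
        X = np.column_stack([np.ones(6), np.r_[np.zeros(3), np.ones(3)] + 0.0])
        X[:, 1] += np.array([0.1, -0.1, 0.0, 0.1, -0.1, 0.0])
        t, p = source_ttest(X, ["F", "F", "F", "M", "M", "M"])
        assert np.isnan(t[0]) and p[0] == 1.0
        assert np.isfinite(t[1])

    def test_matches_scipy(self, rng):
        from scipy import stats
        X = rng.standard_normal((12, 7))
        g = np.array(["F"] * 5 + ["M"] * 7)
        t, p = source_ttest(X, g)
        ref = stats.ttest_ind(X[:5], X[5:], equal_var=True)
        assert np.allclose(t, ref.statistic)
        assert np.allclose(p, ref.pvalue)


class TestSourceCorrelation:
    def test_perfect_correlation(self):
        v = np.arange(6.0)
        r, p = source_correlation(v[:, None], v)
        assert r[0] == pytest.approx(1.0)
        r, _ = source_correlation((-v)[:, None], v)
        assert r[0] == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        values = np.arange(1.0, 7.0)[:, None]
        cov = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        r, _ = source_correlation(values, cov)
        assert r[0] == pytest.approx(0.8286, abs=1e-4)

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(ValueError):
            source_correlation(rng.standard_normal((6, 2)), np.ones(6))

    def test_constant_source_flagged(self, rng):
        X = np.column_stack([np.ones(6), rng.standard_normal(6)])
        r, p = source_correlation(X, np.arange(6.0))
        assert np.isnan(r[0]) and p[0] == 1.0

    def test_matches_scipy(self, rng):
        from scipy import stats
        X = rng.standard_normal((10, 4))
        cov = rng.standard_normal(10)
        r, p = source_correlation(X, cov)
        for j in range(4):
            ref = stats.pearsonr(cov, X[:, j])
            assert r[j] == pytest.approx(ref.statistic)
            assert p[j] == pytest.approx(ref.pvalue)


class TestFormClusters:
    def test_no_significant_sources(self, small_grid):
        stat = np.zeros(27)
        p = np.ones(27)
        assert form_clusters(stat, p, 0.05, small_grid) == []

    def test_opposite_corners_are_singletons(self, small_grid):
        stat = np.zeros(27)
        p = np.ones(27)
        stat[[0, 26]] = 3.0
        p[[0, 26]] = 0.01
        clusters = form_clusters(stat, p, 0.05, small_grid)
        assert sorted(tuple(c[0]) for c in clusters) == [(0,), (26,)]

    def test_l_shaped_cluster_stat_is_member_sum(self):
        grid = make_grid((3, 3, 1), 10.0, 1, seed=0)
        # indices 0,1,4 form an L (row-major on x-major layout: 0-(0,0),1-(0,1),3-(1,0))
        members = [0, 1, 4]
        stat = np.zeros(9)
        p = np.ones(9)
        stat[members] = [2.0, 3.0, 4.0]
        p[members] = 0.01
        clusters = form_clusters(stat, p, 0.05, grid)
        assert len(clusters) == 1
        src, total, sign = clusters[0]
        assert sorted(src) == members and total == pytest.approx(9.0) and sign == 1

    def test_sign_split(self, small_grid):
        stat = np.zeros(27)
        p = np.ones(27)
        stat[[0, 1]] = 3.0
        stat[[2]] = -3.0  # adjacent to 1 but opposite sign
        p[[0, 1, 2]] = 0.01
        clusters = form_clusters(stat, p, 0.05, small_grid)
        assert sorted((tuple(c[0]), c[2]) for c in clusters) == [((0, 1), 1), ((2,), -1)]

    def test_matches_bfs_oracle_on_random_masks(self, flat_grid, rng):
        adjacency = flat_grid.adjacency()
        for _ in range(100):
            p = rng.uniform(size=flat_grid.n_sources)
            stat = np.abs(rng.standard_normal(flat_grid.n_sources)) + 0.1
            clusters = form_clusters(stat, p, 0.3, flat_grid)
            expected = connected_components(np.flatnonzero(p < 0.3), adjacency)
            assert sorted(frozenset(int(s) for s in c[0]) for c in clusters) == \
                sorted(expected)
            for src, total, _ in clusters:
                assert total == pytest.approx(stat[src].sum())


class TestEffectSizes:
    def test_cohens_d_hand_example(self):
        X = np.array([[1.0], [2.0], [3.0], [2.0], [3.0], [4.0]])
        g = ["F", "F", "F", "M", "M", "M"]
        assert cohens_d(X, [0], g) == pytest.approx(-1.0)

    def test_cohens_d_location_invariance(self, rng):
        X = rng.standard_normal((10, 4))
        g = ["F"] * 5 + ["M"] * 5
        d1 = cohens_d(X, [0, 2], g)
        d2 = cohens_d(X + 11.5, [0, 2], g)
        assert d1 == pytest.approx(d2)

    def test_cohens_d_identical_groups_zero(self):
        X = np.tile(np.arange(4.0)[:, None], (2, 3))
        assert cohens_d(X, [0, 1], ["F"] * 4 + ["M"] * 4) == pytest.approx(0.0)

    def test_cluster_mean_rho(self, rng):
        cov = rng.standard_normal(12)
        X = np.column_stack([cov * 2 + rng.standard_normal(12) * 0.1,
                             -cov + rng.standard_normal(12) * 0.1,
                             rng.standard_normal(12)])
        r, _ = source_correlation(X, cov)
        assert cluster_mean_rho(X, [0], cov) == pytest.approx(r[0])
        assert cluster_mean_rho(X, [0, 1, 2], cov) == pytest.approx(r.mean())


@pytest.fixture(scope="module")
def planted_map():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((24, 27)) * 0.1
    X[:12, [22, 23, 25, 26]] += 0.25  # contiguous posterior patch
    g = np.array(["F"] * 12 + ["M"] * 12)
    return X, g


class TestCBPT:
    def test_detects_planted_group_cluster(self, planted_map, small_grid):
        X, g = planted_map
        res = cbpt(X, g, small_grid, mode="group", n_perm=500, seed=1)
        assert res and res[0].significant
        assert {22, 23, 25, 26} <= set(int(s) for s in res[0].sources)
        assert res[0].sign == 1
        assert res[0].effect_size > 0.5  # Cohen's d of a strong planted shift

    def test_cluster_stat_is_sorted_and_valid(self, planted_map, small_grid):
        X, g = planted_map
        res = cbpt(X, g, small_grid, mode="group", n_perm=200, seed=3)
        stats = [abs(r.cluster_stat) for r in res]
        assert stats == sorted(stats, reverse=True)
        for r in res:
            assert 0 < r.p_value <= 1.0
            assert r.p_value >= 1.0 / 201  # +1 correction: never exactly 0

    def test_determinism(self, planted_map, small_grid):
        X, g = planted_map
        a = cbpt(X, g, small_grid, n_perm=200, seed=7)
        b = cbpt(X, g, small_grid, n_perm=200, seed=7)
        assert [(tuple(x.sources), x.p_value) for x in a] == \
               [(tuple(x.sources), x.p_value) for x in b]

    def test_correlation_mode_recovers_design(self, small_grid, rng):
        cov = rng.standard_normal(30)
        X = rng.standard_normal((30, 27)) * 0.5
        X[:, [0, 1, 3, 9]] += cov[:, None] * 1.0
        res = cbpt(X, cov, small_grid, mode="correlation", n_perm=500, seed=2)
        assert res and res[0].significant
        assert {0, 1, 3, 9} <= set(int(s) for s in res[0].sources)
        assert res[0].effect_size > 0.3  # mean rho over the cluster

    def test_monotone_cluster_growth(self, small_grid):
        # adding a same-sign significant neighbor increases |cluster stat|
        stat = np.zeros(27)
        p = np.ones(27)
        stat[[0, 1]] = [2.5, 2.5]
        p[[0, 1]] = 0.01
        small = form_clusters(stat, p, 0.05, small_grid)
        stat[2] = 2.5
        p[2] = 0.01
        grown = form_clusters(stat, p, 0.05, small_grid)
        assert abs(grown[0][1]) > abs(small[0][1])

    def test_degenerate_designs_rejected(self, small_grid, rng):
        X = rng.standard_normal((6, 27))
        with pytest.raises(ValueError):
            cbpt(X, ["F"] * 6, small_grid, n_perm=100)
        with pytest.raises(ValueError):
            cbpt(X, ["F", "M", "F", "M", "F", "M"], small_grid, n_perm=10)

    def test_group_and_correlation_engines_agree_on_dichotomous_covariate(
            self, small_grid, rng):
        # a two-level covariate makes the correlation statistic a monotone
        # transform of t: the same sources must enter the observed clusters
        X = rng.standard_normal((20, 27)) * 0.2
        X[:10, [22, 23, 25, 26]] += 0.5
        g = np.array(["F"] * 10 + ["M"] * 10)
        cov = (g == "F").astype(float)
        res_g = cbpt(X, g, small_grid, mode="group", n_perm=300, seed=5)
        res_c = cbpt(X, cov, small_grid, mode="correlation", n_perm=300, seed=5)
        assert [tuple(r.sources) for r in res_g] == [tuple(r.sources) for r in res_c]
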