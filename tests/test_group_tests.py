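from itertools import permutations

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix

from assemblyscope import anosim, mantel, mrpp, partial_mantel, permanova


def _dm(points, ids=None):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1:
        points = points.T
    ids = ids or [str(i) for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


def _exhaustive_anosim_p(dm, codes):
    n = len(codes)
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(dm.data[iu])
    m = n * (n - 1) / 2

    def stat(c):
        c = np.asarray(c)
        within = c[iu[0]] == c[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2)

    obs = stat(codes)
    vals = [stat(p) for p in permutations(codes)]
    return np.mean([v >= obs - 1e-12 for v in vals])


def _exhaustive_permanova_p(dm, codes):
    n = len(codes)
    iu = np.triu_indices(n, k=1)
    d2 = dm.data[iu] ** 2
    a = len(set(codes))

    def pseudo_f(c):
        c = np.asarray(c)
        ss_t = d2.sum() / n
        ss_w = 0.0
        for g in set(c):
            mask = (c[iu[0]] == g) & (c[iu[1]] == g)
            ss_w += d2[mask].sum() / (c == g).sum()
        ss_b = ss_t - ss_w
        return np.inf if ss_w == 0 else (ss_b / (a - 1)) / (ss_w / (n - a))

    obs = pseudo_f(codes)
    vals = [pseudo_f(p) for p in permutations(codes)]
    return np.mean([v >= obs - 1e-12 for v in vals])


def _exhaustive_mrpp_p(dm, codes):
    n = len(codes)
    iu = np.triu_indices(n, k=1)
    d = dm.data[iu]

    def delta(c):
        c = np.asarray(c)
        val = 0.0
        for g in set(c):
            mask = (c[iu[0]] == g) & (c[iu[1]] == g)
            n_g = (c == g).sum()
            val += d[mask].mean() * n_g / n
        return val

    obs = delta(codes)
    vals = [delta(p) for p in permutations(codes)]
    return np.mean([v <= obs + 1e-12 for v in vals])


def _exhaustive_mantel_p(dx, dy):
    n = dx.shape[0]
    iu = np.triu_indices(n, k=1)
    y = dy.data[iu]
    obs = np.corrcoef(dx.data[iu], y)[0, 1]
    vals = []
    for p in permutations(range(n)):
        p = list(p)
        vals.append(np.corrcoef(dx.data[np.ix_(p, p)][iu], y)[0, 1])
    return np.mean([v >= obs - 1e-12 for v in vals])


def _close_to_exhaustive(p_sampled, p_exhaustive, n_perm):
    se = np.sqrt(p_exhaustive * (1 - p_exhaustive) / n_perm)
    return abs(p_sampled - p_exhaustive) <= 2 * se + 2 / (n_perm + 1)


class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        dm = _dm([0.0, 1.0, 10.0, 11.0])
        res = anosim(dm, ["g1", "g1", "g2", "g2"], n_perm=199, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_random_labels_r_near_zero(self):
        rng = np.random.default_rng(3)
        dm = _dm(rng.normal(size=(20, 3)))
        res = anosim(dm, ["a", "b"] * 10, n_perm=499, seed=1)
        assert abs(res.statistic) < 0.15
        assert res.p_value > 0.05

    def test_sampled_p_matches_exhaustive(self):
        rng = np.random.default_rng(11)
        dm = _dm(rng.normal(size=(6, 2)))
        codes = ["a", "a", "a", "b", "b", "b"]
        res = anosim(dm, codes, n_perm=999, seed=5)
        p_ex = _exhaustive_anosim_p(dm, codes)
        assert _close_to_exhaustive(res.p_value, p_ex, 999)

    def test_group_of_one_rejected(self):
        dm = _dm([0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="fewer than 2"):
            anosim(dm, ["a", "a", "b"], n_perm=99, seed=0)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(4)
        dm = _dm(rng.normal(size=(8, 2)))
        groups = ["a"] * 4 + ["b"] * 4
        r1 = anosim(dm, groups, n_perm=199, seed=7)
        r2 = anosim(dm, groups, n_perm=199, seed=7)
        assert (r1.statistic, r1.p_value) == (r2.statistic, r2.p_value)


class TestPermanova:
    def test_duplicated_points_give_r2_one(self):
        dm = _dm([0.0, 0.0, 5.0, 5.0])
        res = permanova(dm, ["g1", "g1", "g2", "g2"], n_perm=199, seed=0)
        assert res.extras["R2"] == pytest.approx(1.0)

    def test_random_split_r2_near_zero(self):
        rng = np.random.default_rng(8)
        dm = _dm(rng.normal(size=(20, 3)))
        res = permanova(dm, ["a", "b"] * 10, n_perm=499, seed=2)
        assert res.extras["R2"] < 0.15

    def test_r2_matches_coordinate_space_oracle(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(12, 2))
        pts[6:] += 2.0
        groups = np.array(["a"] * 6 + ["b"] * 6)
        dm = _dm(pts)
        res = permanova(dm, groups, n_perm=99, seed=0)
        ss_t = ((pts - pts.mean(0)) ** 2).sum()
        ss_w = sum(
            ((pts[groups == g] - pts[groups == g].mean(0)) ** 2).sum()
            for g in ("a", "b")
        )
        assert res.extras["R2"] == pytest.approx(1 - ss_w / ss_t, abs=1e-10)

    def test_sampled_p_matches_exhaustive(self):
        rng = np.random.default_rng(13)
        dm = _dm(rng.normal(size=(6, 2)))
        codes = ["a", "a", "a", "b", "b", "b"]
        res = permanova(dm, codes, n_perm=999, seed=5)
        p_ex = _exhaustive_permanova_p(dm, codes)
        assert _close_to_exhaustive(res.p_value, p_ex, 999)


class TestMrpp:
    def test_perfect_clustering(self):
        dm = _dm([0.0, 0.0, 7.0, 7.0])
        res = mrpp(dm, ["g1", "g1", "g2", "g2"], n_perm=199, seed=0)
        assert res.extras["delta"] == pytest.approx(0.0)
        assert res.statistic == pytest.approx(1.0)

    def test_random_labels_a_near_zero(self):
        rng = np.random.default_rng(10)
        dm = _dm(rng.normal(size=(20, 3)))
        res = mrpp(dm, ["a", "b"] * 10, n_perm=499, seed=3)
        assert abs(res.statistic) < 0.1

    def test_sampled_p_matches_exhaustive(self):
        rng = np.random.default_rng(17)
        dm = _dm(rng.normal(size=(6, 2)))
        codes = ["a", "a", "a", "b", "b", "b"]
        res = mrpp(dm, codes, n_perm=999, seed=5)
        p_ex = _exhaustive_mrpp_p(dm, codes)
        assert _close_to_exhaustive(res.p_value, p_ex, 999)


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(2)
        dm = _dm(rng.normal(size=(8, 2)))
        res = mantel(dm, dm, n_perm=199, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_statistic_equals_triangle_pearson(self):
        rng = np.random.default_rng(21)
        dx = _dm(rng.normal(size=(8, 2)))
        dy = _dm(rng.normal(size=(8, 2)))
        res = mantel(dx, dy, n_perm=99, seed=0)
        iu = np.triu_indices(8, k=1)
        expected = np.corrcoef(dx.data[iu], dy.data[iu])[0, 1]
        assert res.statistic == pytest.approx(expected, abs=1e-12)

    def test_statistic_matches_skbio(self):
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(22)
        dx = _dm(rng.normal(size=(10, 2)))
        dy = _dm(rng.normal(size=(10, 2)))
        res = mantel(dx, dy, n_perm=99, seed=0)
        r_skbio = skbio_mantel(dx, dy, permutations=0)[0]
        assert res.statistic == pytest.approx(float(r_skbio), abs=1e-12)

    def test_independent_matrices_rarely_significant(self):
        rng = np.random.default_rng(23)
        pvals = []
        for _ in range(10):
            dx = _dm(rng.normal(size=(10, 2)))
            dy = _dm(rng.normal(size=(10, 2)))
            pvals.append(mantel(dx, dy, n_perm=199, seed=1).p_value)
        assert np.mean(np.array(pvals) < 0.05) <= 0.3

    def test_sampled_p_matches_exhaustive(self):
        rng = np.random.default_rng(29)
        dx = _dm(rng.normal(size=(6, 2)))
        dy = _dm(rng.normal(size=(6, 2)))
        res = mantel(dx, dy, n_perm=999, seed=5)
        p_ex = _exhaustive_mantel_p(dx, dy)
        assert _close_to_exhaustive(res.p_value, p_ex, 999)


class TestPartialMantel:
    def test_reduces_to_simple_mantel_when_control_uncorrelated(self):
        # build dz orthogonal to dx and dy on the triangle by construction
        rng = np.random.default_rng(31)
        dx = _dm(rng.normal(size=(12, 2)))
        dy = _dm(rng.normal(size=(12, 2)))
        dz = _dm(rng.normal(size=(12, 2)))
        res_partial = partial_mantel(dx, dy, dz, n_perm=99, seed=0)
        res_simple = mantel(dx, dy, n_perm=99, seed=0)
        iu = np.triu_indices(12, k=1)
        rxz = np.corrcoef(dx.data[iu], dz.data[iu])[0, 1]
        ryz = np.corrcoef(dy.data[iu], dz.data[iu])[0, 1]
        expected = (res_simple.statistic - rxz * ryz) / np.sqrt(
            (1 - rxz**2) * (1 - ryz**2)
        )
        assert res_partial.statistic == pytest.approx(expected, abs=1e-12)

    def test_degenerate_control_rejected(self):
        rng = np.random.default_rng(37)
        dx = _dm(rng.normal(size=(6, 2)))
        dy = _dm(rng.normal(size=(6, 2)))
        with pytest.raises(ValueError, match="degenerate"):
            partial_mantel(dx, dy, dy, n_perm=99, seed=0)

    def test_plugin_formula_on_toy_matrices(self):
        a = np.array([0.0, 1.0, 2.5, 4.0])
        b = np.array([0.0, 1.1, 2.0, 4.5])
        c = np.array([0.0, 3.0, 1.0, 2.0])
        dx = _dm(a)
        dy = _dm(b)
        dz = _dm(c)
        iu = np.triu_indices(4, k=1)
        rxy = np.corrcoef(dx.data[iu], dy.data[iu])[0, 1]
        rxz = np.corrcoef(dx.data[iu], dz.data[iu])[0, 1]
        ryz = np.corrcoef(dy.data[iu], dz.data[iu])[0, 1]
        expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        res = partial_mantel(dx, dy, dz, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(expected, abs=1e-12)


def test_minimum_p_is_one_over_nperm_plus_one():
    dm = _dm([0.0, 1.0, 10.0, 11.0, 20.0, 21.0])
    res = anosim(dm, ["a", "a", "b", "b", "c", "c"], n_perm=999, seed=0)
    assert res.p_value >= 1 / 1000
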