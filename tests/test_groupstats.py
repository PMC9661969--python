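import numpy as np
import pytest
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from ecoassembly import SampleMetadata
from ecoassembly.groupstats import (
    bh_adjust,
    dunn_test,
    geographic_distances,
    kruskal_wallis,
    pairwise_permanova,
    permanova,
)


def random_distance_matrix(n, seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix(d, ids=[f"s{i}" for i in range(n)])


class TestPermanova:
    def test_p_respects_add_one_floor(self):
        d = random_distance_matrix(8, 0)
        res = permanova(d, ["a"] * 4 + ["b"] * 4, n_perm=99, seed=1)
        assert res.p_value >= 1 / 100

    def test_statistic_matches_skbio(self):
        for seed in range(5):
            d = random_distance_matrix(9, seed)
            groups = ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
            ours = permanova(d, groups, n_perm=9, seed=0)
            ref = skbio_permanova(d, grouping=groups, permutations=9)
            assert ours.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_group_of_one_errors(self):
        d = random_distance_matrix(5, 2)
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(d, ["a", "a", "a", "a", "b"], n_perm=9, seed=0)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for i in range(40):
            d = random_distance_matrix(8, 100 + i)
            groups = list(rng.permutation(["a"] * 4 + ["b"] * 4))
            ps.append(permanova(d, groups, n_perm=99, seed=i).p_value)
        # labels are exchangeable: small p should appear at roughly alpha rate
        assert 0.0 <= np.mean(np.array(ps) < 0.1) <= 0.3


class TestPairwisePermanova:
    def test_four_levels_give_six_comparisons(self):
        d = random_distance_matrix(12, 4)
        groups = ["a", "b", "c", "d"] * 3
        table = pairwise_permanova(d, groups, n_perm=19, seed=0)
        assert len(table) == 6

    def test_adjusted_at_least_raw(self):
        d = random_distance_matrix(12, 5)
        groups = ["a", "b", "c", "d"] * 3
        table = pairwise_permanova(d, groups, n_perm=19, seed=0)
        assert (table["p_adjusted"] >= table["p_value"] - 1e-12).all()


class TestBHAdjust:
    def test_hand_step_up(self):
        adj = bh_adjust([0.01, 0.02, 0.03])
        assert adj == pytest.approx([0.03, 0.03, 0.03])

    def test_ties_at_max_rank_unchanged(self):
        adj = bh_adjust([0.2, 0.2, 0.2])
        assert adj == pytest.approx([0.2, 0.2, 0.2])

    def test_monotone_in_raw_p(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(8)
            adj = bh_adjust(p)
            order = np.argsort(p)
            assert (np.diff(adj[order]) >= -1e-12).all()


class TestKruskalWallis:
    def test_hand_two_group_value(self):
        res = kruskal_wallis([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert res.statistic == pytest.approx(3.857, abs=1e-3)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=15)
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        res = kruskal_wallis(vals, groups)
        h, p = stats.kruskal(vals[:5], vals[5:10], vals[10:])
        assert res.statistic == pytest.approx(h)
        assert res.p_value == pytest.approx(p)

    def test_identical_values_h_zero(self):
        res = kruskal_wallis([2, 2, 2, 2], ["a", "a", "b", "b"])
        assert res.statistic == 0.0
        assert res.p_value == 1.0


class TestDunnTest:
    def test_two_group_z_squared_equals_kw_h(self):
        vals = [3.1, 4.2, 1.0, 9.9, 7.3, 8.8]
        groups = ["a", "a", "a", "b", "b", "b"]
        dunn = dunn_test(vals, groups)
        kw = kruskal_wallis(vals, groups)
        assert dunn.iloc[0]["z"] ** 2 == pytest.approx(kw.statistic)

    def test_two_group_equivalence_with_ties(self):
        vals = [1, 1, 2, 2, 2, 5, 5, 7]
        groups = ["a"] * 4 + ["b"] * 4
        dunn = dunn_test(vals, groups)
        kw = kruskal_wallis(vals, groups)
        assert dunn.iloc[0]["z"] ** 2 == pytest.approx(kw.statistic)

    def test_identical_groups_large_adjusted_p(self):
        vals = [1, 2, 3] * 3
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        dunn = dunn_test(vals, groups)
        assert (dunn["p_adjusted"] > 0.8).all()

    def test_matches_formula_oracle(self):
        vals = np.array([1.0, 2.0, 2.0, 4.0, 5.0, 7.0, 7.0, 9.0, 10.0])
        groups = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        dunn = dunn_test(vals, groups)
        # independent oracle: explicit rank arithmetic
        order = np.argsort(vals, kind="mergesort")
        ranks = np.empty(len(vals))
        i = 0
        sorted_vals = vals[order]
        while i < len(vals):
            j = i
            while j < len(vals) and sorted_vals[j] == sorted_vals[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0
            i = j
        n = len(vals)
        ties = [np.sum(vals == v) for v in np.unique(vals)]
        tie_term = sum(t**3 - t for t in ties)
        var = n * (n + 1) / 12 - tie_term / (12 * (n - 1))
        ra = ranks[groups == "a"].mean()
        rb = ranks[groups == "b"].mean()
        z_ab = (ra - rb) / np.sqrt(var * (1 / 3 + 1 / 3))
        row = dunn[(dunn["group_a"] == "a") & (dunn["group_b"] == "b")].iloc[0]
        assert row["z"] == pytest.approx(z_ab)


class TestGeographicDistances:
    def _meta(self, coords):
        return [
            SampleMetadata(f"l{i}", lat, lon, "public")
            for i, (lat, lon) in enumerate(coords)
        ]

    def test_identical_coordinates_zero(self):
        d = geographic_distances(self._meta([(-43.5, 170.1), (-43.5, 170.1)]))
        assert d["l0", "l1"] == pytest.approx(0.0)

    def test_antipodal_half_circumference(self):
        d = geographic_distances(self._meta([(0.0, 0.0), (0.0, 180.0)]))
        assert d["l0", "l1"] == pytest.approx(6371 * np.pi, rel=1e-6)

    def test_symmetry_and_zero_diagonal(self):
        d = geographic_distances(
            self._meta([(-43.0, 170.0), (-44.2, 169.5), (-42.7, 171.9)])
        )
        assert np.allclose(d.data, d.data.T)
        assert np.allclose(np.diag(d.data), 0.0)
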