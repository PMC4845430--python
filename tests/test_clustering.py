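import numpy as np
import pandas as pd
import pytest

from genetrends import (
    crossmatch_itemsets,
    fcm,
    fuzzy_area_genes,
    hierarchical_complete,
    pca_2d,
    validity,
)
from genetrends.clustering import _fcm_memberships, suggest_c, validity_scan
from genetrends.pattern_mining import MinedItemset


def frame(rows, labels=None):
    data = np.asarray(rows, dtype=float)
    labels = labels or [f"row{i}" for i in range(data.shape[0])]
    return pd.DataFrame(data, index=labels)


def brute_force_complete_link(data, metric="euclidean"):
    """Oracle agglomeration: recompute every max-linkage distance from the
    raw points at every step (no incremental update)."""
    pts = {i: [i] for i in range(len(data))}

    def d(i, j):
        if metric == "euclidean":
            return float(np.linalg.norm(np.asarray(data[i]) - np.asarray(data[j])))
        raise ValueError(metric)

    merges = []
    next_id = len(data)
    while len(pts) > 1:
        best = None
        for a in sorted(pts):
            for b in sorted(pts):
                if a >= b:
                    continue
                h = max(d(i, j) for i in pts[a] for j in pts[b])
                if best is None or (h, (a, b)) < best:
                    best = (h, (a, b))
        h, (a, b) = best
        pts[next_id] = pts.pop(a) + pts.pop(b)
        merges.append((a, b, h, next_id))
        next_id += 1
    return merges


class TestHierarchicalComplete:
    def test_three_points_on_a_line(self):
        # pair distances: d(0,1)=1, d(1,10)=9, d(0,10)=10 -> merge {0,1}
        # at height 1, then complete-link height max(9, 10) = 10
        dendro = hierarchical_complete(frame([[0.0], [1.0], [10.0]]),
                                       metric="euclidean")
        assert dendro.merges[0][:3] == (0, 1, 1.0)
        assert dendro.merges[1][2] == 10.0

    def test_identical_rows_merge_at_zero(self):
        dendro = hierarchical_complete(frame([[1, 2], [1, 2], [5, 9]]),
                                       metric="euclidean")
        assert dendro.merges[0][:3] == (0, 1, 0.0)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(4)
        dendro = hierarchical_complete(frame(rng.normal(size=(9, 3))),
                                       metric="euclidean")
        heights = [m[2] for m in dendro.merges]
        assert heights == sorted(heights)
        assert len(dendro.merges) == 8  # n - 1

    def test_asymmetric_metric_rejected(self):
        calls = {"n": 0}

        def bad_metric(x, y):
            calls["n"] += 1
            return float(x[0] - y[0])  # antisymmetric, not a metric

        with pytest.raises(ValueError, match="symmetry"):
            hierarchical_complete(frame([[0.0], [3.0]]), metric=bad_metric)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_complete(frame([[1.0]]))

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_from_scratch_agglomeration(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(8, 2))
        dendro = hierarchical_complete(frame(data), metric="euclidean")
        expected = brute_force_complete_link(data.tolist())
        for got, exp in zip(dendro.merges, expected):
            assert got[0] == exp[0] and got[1] == exp[1]
            assert got[2] == pytest.approx(exp[2])

    def test_newick_output_parses(self):
        dendro = hierarchical_complete(
            frame([[0.0], [1.0], [10.0]], labels=["x", "y", "z"]),
            metric="euclidean",
        )
        nwk = dendro.to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 2
        assert {"x", "y", "z"} <= set(nwk.replace("(", " ").replace(")", " ")
                                      .replace(",", " ").replace(":", " ").split()
                                      ) | {"x", "y", "z"}


def two_clouds(n_per=20, sep=40.0, spread=1.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, spread, size=(n_per, 2))
    b = rng.normal(sep, spread, size=(n_per, 2))
    return np.vstack([a, b])


class TestFCM:
    def test_separated_clouds_memberships_confident(self):
        # clouds at >= 20x spread; checked against a direct evaluation of
        # the membership update formula at the returned centers
        x = two_clouds()
        res = fcm(x, c=2, seed=3)
        top = res.membership.max(axis=0)
        assert (top > 0.95).all()
        direct = _fcm_memberships(x, res.centers, res.fuzzifier)
        assert np.allclose(direct, res.membership)
        # fixed point: recomputing centers from U reproduces the centers
        um = res.membership**res.fuzzifier
        recon = (um @ x) / um.sum(axis=1)[:, None]
        assert np.allclose(recon, res.centers, atol=1e-3)

    def test_identical_points_give_uniform_memberships(self):
        x = np.ones((6, 2))
        res = fcm(x, c=3, seed=0)
        assert np.allclose(res.centers, 1.0)
        assert np.allclose(res.membership, 1.0 / 3)

    def test_same_seed_identical_result(self):
        x = two_clouds(seed=5)
        a = fcm(x, c=2, seed=11)
        b = fcm(x, c=2, seed=11)
        assert np.array_equal(a.membership, b.membership)
        assert a.objective == b.objective

    def test_membership_columns_sum_to_one(self):
        res = fcm(two_clouds(seed=2), c=4, seed=1)
        assert np.allclose(res.membership.sum(axis=0), 1.0)

    def test_objective_non_increasing(self):
        res = fcm(two_clouds(seed=7), c=3, seed=9)
        hist = res.objective_history
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))

    def test_point_on_center_gets_full_membership(self):
        x = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 0.0]])
        res = fcm(x, c=2, seed=0, max_iter=5)
        # the point coincident with a center is crisply assigned
        u = _fcm_memberships(x, np.array([[0.0, 0.0], [10.0, 0.0]]), 2.0)
        assert u[0, 0] == 1.0 and u[1, 0] == 0.0

    def test_parameter_bounds_validated(self):
        x = two_clouds()
        with pytest.raises(ValueError):
            fcm(x, c=1)
        with pytest.raises(ValueError):
            fcm(x, c=2, m=1.0)


class TestValidity:
    def test_hard_partition_pc_one_ce_zero(self):
        x = np.array([[0.0], [0.1], [10.0], [10.1]])
        u = np.array([[1.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 1.0]])
        res_like = {
            2: type("R", (), {
                "membership": u, "fuzzifier": 2.0,
                "centers": np.array([[0.05], [10.05]]),
            })()
        }
        table = validity(x, res_like)
        assert table.loc[2, "PC"] == pytest.approx(1.0)
        assert table.loc[2, "CE"] == pytest.approx(0.0)

    def test_uniform_partition_pc_inverse_c_ce_log_c(self):
        x = np.array([[0.0], [1.0], [2.0]])
        for c in (2, 3):
            u = np.full((c, 3), 1.0 / c)
            res_like = {c: type("R", (), {
                "membership": u, "fuzzifier": 2.0,
                "centers": np.linspace(0, 2, c).reshape(-1, 1),
            })()}
            table = validity(x, res_like)
            assert table.loc[c, "PC"] == pytest.approx(1.0 / c)
            assert table.loc[c, "CE"] == pytest.approx(np.log(c))

    def test_xbi_prefers_true_cluster_count_on_two_clouds(self):
        x = two_clouds(seed=8)
        table, _ = validity_scan(x, c_min=2, c_max=5, seed=6)
        assert table.loc[2, "XBI"] < table.loc[5, "XBI"]

    def test_duplicate_centers_give_nan_xbi(self):
        x = np.array([[0.0], [1.0], [2.0]])
        u = np.full((2, 3), 0.5)
        res_like = {2: type("R", (), {
            "membership": u, "fuzzifier": 2.0,
            "centers": np.array([[1.0], [1.0]]),
        })()}
        assert np.isnan(validity(x, res_like).loc[2, "XBI"])

    def test_pc_bounds_hold_on_fcm_output(self):
        x = two_clouds(seed=12)
        table, _ = validity_scan(x, c_min=2, c_max=4, seed=2)
        for c in table.index:
            assert 1.0 / c - 1e-9 <= table.loc[c, "PC"] <= 1.0 + 1e-9
            assert table.loc[c, "CE"] >= -1e-9

    def test_pi_elbow_at_planted_cluster_count(self):
        """3 well-separated clouds: the PI elbow over c in 2..6 sits at 3."""
        rng = np.random.default_rng(21)
        x = np.vstack([
            rng.normal((0, 0), 1.0, size=(15, 2)),
            rng.normal((30, 0), 1.0, size=(15, 2)),
            rng.normal((0, 30), 1.0, size=(15, 2)),
        ])
        table, results = validity_scan(x, c_min=2, c_max=6, seed=4)
        assert suggest_c(table) == 3  # elbow: largest relative PI drop
        # FCM with c=3 recovers the planted centers within the spread
        centers = np.sort(results[3].centers.round(0), axis=0)
        expected = np.sort(np.array([[0, 0], [30, 0], [0, 30]]), axis=0)
        assert np.allclose(centers, expected, atol=1.5)


class TestPCA:
    def test_centered_2d_data_preserves_pairwise_distances(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10, 2))
        x -= x.mean(axis=0)
        coords = pca_2d(x)
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(coords), pdist(x))

    def test_collinear_points_second_axis_zero(self):
        x = np.outer(np.arange(6, dtype=float), [1.0, 2.0])
        with pytest.warns(UserWarning):
            coords = pca_2d(x)
        assert np.allclose(coords[:, 1], 0.0, atol=1e-9)

    def test_first_axis_variance_dominates(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(30, 5)) * np.array([5, 1, 1, 1, 1])
        coords = pca_2d(x)
        assert coords[:, 0].var() >= coords[:, 1].var()

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(12, 4))
        assert np.array_equal(pca_2d(x), pca_2d(x.copy()))


class TestFuzzyArea:
    def test_threshold_classification(self):
        u = np.array([[0.5, 0.9, 0.55], [0.5, 0.1, 0.45]])
        assert fuzzy_area_genes(u, ["a", "b", "c"], tau=0.6) == {"a", "c"}

    def test_tau_one_excludes_only_crisp_memberships(self):
        u = np.array([[1.0, 0.7], [0.0, 0.3]])
        assert fuzzy_area_genes(u, ["crisp", "soft"], tau=1.0) == {"soft"}


class TestCrossmatch:
    def itemset(self, *items):
        return MinedItemset(items=tuple(items), support_count=1, support_pct=50.0)

    def test_fraction_of_members_in_fuzzy_area(self):
        table = crossmatch_itemsets(
            [self.itemset("A", "B"), self.itemset("C", "D"),
             self.itemset("A", "B", "C")],
            fuzzy_area={"A", "B"},
        )
        assert table["fuzzy_fraction"].tolist() == [1.0, 0.0, pytest.approx(2 / 3)]

    def test_genes_missing_from_universe_reported(self):
        table = crossmatch_itemsets(
            [self.itemset("A", "Z")], fuzzy_area={"A"}, universe={"A", "B"},
        )
        assert table.loc[0, "fuzzy_fraction"] == 1.0
        assert table.loc[0, "missing"] == "Z"
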