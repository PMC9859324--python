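"""Ward clustering, between-cluster tests and dendrogram export."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from oxylife.cluster import (YLLMatrix, compare_clusters, cut_tree,
                             export_dendrogram, kruskal_wallis, ward_cluster)
from oxylife.synthetic import SyntheticConfig, generate_yll


def _ward_ess_oracle(X):
    """Greedy Ward merges by exhaustive minimum ESS-increase search.

    Returns the merge heights sqrt(2 * delta ESS) in order, the convention
    used by the implementation (and scipy).
    """
    clusters = {i: [i] for i in range(len(X))}

    def ess(members):
        pts = X[members]
        return ((pts - pts.mean(axis=0)) ** 2).sum()

    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            delta = (ess(clusters[a] + clusters[b]) - ess(clusters[a])
                     - ess(clusters[b]))
            if best is None or delta < best[0] - 1e-12:
                best = (delta, a, b)
        delta, a, b = best
        heights.append(np.sqrt(2 * delta))
        clusters[min(a, b)] = clusters.pop(a) + clusters.pop(b)
    return np.array(heights)


class TestWard:
    def test_identical_rows_merge_first_at_zero(self):
        X = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [50.0, 60.0]])
        res = ward_cluster(X, k=1)
        assert set(res.linkage[0, :2]) == {0, 1}
        assert res.linkage[0, 2] == 0.0

    def test_three_points_merge_order_and_heights(self):
        X = pd.DataFrame({"v": [0.0, 1.0, 10.0]})
        res = ward_cluster(X, k=1)
        assert set(res.linkage[0, :2]) == {0, 1}
        oracle = _ward_ess_oracle(X.to_numpy())
        assert res.linkage[:, 2] == pytest.approx(oracle, rel=1e-10)

    @pytest.mark.parametrize("n, d, seed", [(5, 3, 0), (6, 2, 1), (6, 4, 2)])
    def test_matches_brute_force_ess_oracle(self, n, d, seed):
        X = np.random.default_rng(seed).normal(size=(n, d))
        res = ward_cluster(pd.DataFrame(X), k=1)
        assert res.linkage[:, 2] == pytest.approx(_ward_ess_oracle(X),
                                                  rel=1e-9)

    def test_matches_scipy_linkage(self, rng):
        X = rng.normal(size=(20, 6))
        res = ward_cluster(pd.DataFrame(X), k=3)
        ref = hierarchy.linkage(X, method="ward")
        assert res.linkage[:, 2] == pytest.approx(ref[:, 2], rel=1e-8)
        mine = res.labels.to_numpy()
        theirs = hierarchy.fcluster(ref, 3, criterion="maxclust")
        assert _ari(mine, theirs) == pytest.approx(1.0)

    def test_heights_monotone(self, rng):
        X = rng.normal(size=(15, 4))
        res = ward_cluster(pd.DataFrame(X), k=2)
        assert np.all(np.diff(res.linkage[:, 2]) >= -1e-10)

    def test_labels_invariant_to_row_order(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 5)),
                         index=[f"r{i}" for i in range(12)])
        perm = rng.permutation(12)
        a = ward_cluster(X, k=3).labels
        b = ward_cluster(X.iloc[perm], k=3).labels
        joined = pd.DataFrame({"a": a, "b": b.reindex(a.index)})
        assert _ari(joined["a"].to_numpy(), joined["b"].to_numpy()) == 1.0

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            ward_cluster(pd.DataFrame(np.eye(3)), k=4)

    def test_cut_partitions_into_k(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)))
        res = ward_cluster(X, k=4)
        assert sorted(res.labels.unique()) == [1, 2, 3, 4]


def _ari(a, b):
    """Adjusted Rand index (hand implementation for label comparison)."""
    from scipy.special import comb

    ct = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
    sum_comb = comb(ct, 2).sum()
    sum_a = comb(ct.sum(axis=1), 2).sum()
    sum_b = comb(ct.sum(axis=0), 2).sum()
    n = comb(ct.sum(), 2)
    exp = sum_a * sum_b / n
    max_idx = (sum_a + sum_b) / 2
    if max_idx == exp:
        return 1.0
    return (sum_comb - exp) / (max_idx - exp)


class TestKruskalWallis:
    def test_hand_ranked_example(self):
        h, p, method = kruskal_wallis([(1, 2), (3, 4), (5, 6)])
        assert h == pytest.approx(4.5714, abs=1e-3)
        assert method == "exact"

    def test_matches_scipy_h(self, rng):
        from scipy import stats
        groups = [rng.normal(size=7), rng.normal(size=9),
                  rng.normal(1.0, size=6)]
        h, p, method = kruskal_wallis(groups, exact_limit=0)
        ref = stats.kruskal(*groups)
        assert h == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_exact_p_matches_enumeration(self):
        groups = [(1.0, 4.0), (2.0, 6.0), (3.0, 5.0)]
        h_obs, p, method = kruskal_wallis(groups)
        assert method == "exact"
        # oracle: enumerate all distinct assignments of pooled values
        pooled = np.array([v for g in groups for v in g])
        sizes = [2, 2, 2]
        count = total = 0
        for perm in itertools.permutations(range(6)):
            vals = pooled[list(perm)]
            h = kruskal_wallis([vals[:2], vals[2:4], vals[4:]],
                               exact_limit=0)[0]
            total += 1
            count += h >= h_obs - 1e-12
        assert p == pytest.approx(count / total, abs=1e-12)


class TestCompareClusters:
    def test_bonferroni_arithmetic(self, rng):
        # three well-separated normal clusters: ANOVA route, 3 pairs
        X = pd.DataFrame({
            "cause": np.concatenate([rng.normal(0, 1, 8),
                                     rng.normal(0.5, 1, 8),
                                     rng.normal(1.0, 1, 8)])},
            index=[f"r{i}" for i in range(24)])
        labels = pd.Series([1] * 8 + [2] * 8 + [3] * 8, index=X.index)
        tests = compare_clusters(X, labels)
        t = tests[0]
        assert len(t.pairwise) == 3
        for padj in t.pairwise.values():
            assert padj <= 1.0

    def test_skewed_data_routes_nonparametric(self, rng):
        X = pd.DataFrame({"cause": np.exp(rng.normal(0, 1.5, 30)) ** 2},
                         index=[f"r{i}" for i in range(30)])
        labels = pd.Series([1] * 10 + [2] * 10 + [3] * 10, index=X.index)
        tests = compare_clusters(X, labels)
        assert tests[0].route == "kruskal"

    def test_singleton_cluster_skipped_with_warning(self, rng):
        X = pd.DataFrame({"cause": rng.normal(size=9)},
                         index=[f"r{i}" for i in range(9)])
        labels = pd.Series([1] * 4 + [2] * 4 + [3], index=X.index)
        with pytest.warns(UserWarning, match="size < 2"):
            tests = compare_clusters(X, labels)
        assert list(tests[0].pairwise) == [(1, 2)]


class TestDendrogramExport:
    def test_two_leaves_convention(self):
        X = pd.DataFrame([[0.0], [3.0]], index=["A", "B"])
        res = ward_cluster(X, k=1)
        nwk, _ = export_dendrogram(res)
        h = res.linkage[0, 2]
        assert nwk == f"(A:{h / 2:.6g},B:{h / 2:.6g});"

    def test_round_trip_preserves_topology(self, rng):
        import dendropy

        X = pd.DataFrame(rng.normal(size=(8, 3)),
                         index=[f"L{i}" for i in range(8)])
        res = ward_cluster(X, k=1)
        nwk, link_df = export_dendrogram(res)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(tree.leaf_nodes()) == 8
        assert {lf.taxon.label for lf in tree.leaf_nodes()} == set(X.index)
        assert len(link_df) == 7

    def test_34_leaf_synthetic_tree(self):
        cfg = SyntheticConfig()
        Y, labels, _ = generate_yll(cfg, seed=5)
        res = ward_cluster(Y, k=3)
        nwk, _ = export_dendrogram(res)
        assert nwk.count(",") == 33  # n-1 separators for 34 leaves


def test_planted_clusters_recovered():
    cfg = SyntheticConfig(between_cluster_shift=5.0)
    Y, labels, _ = generate_yll(cfg, seed=0)
    res = ward_cluster(Y, k=3)
    assert _ari(res.labels.reindex(labels.index).to_numpy(),
                labels.to_numpy()) == 1.0


def test_yll_matrix_validation():
    with pytest.raises(ValueError, match="non-negative"):
        YLLMatrix(pd.DataFrame([[1.0, -2.0]]))
    with pytest.raises(ValueError, match="missing"):
        YLLMatrix(pd.DataFrame([[1.0, np.nan]]))
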