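"""Spatial weights and Global Moran's I."""

import itertools
import math

import numpy as np
import pytest

from oxylife.spatial import (EARTH_RADIUS_KM, WeightMatrix,
                             great_circle_distance, inverse_distance_weights,
                             morans_i, pairwise_distances)


class TestGreatCircle:
    def test_identical_points(self):
        assert great_circle_distance((10, 20), (10, 20)) == 0.0

    def test_antipodes(self):
        assert great_circle_distance((0, 0), (180, 0)) == pytest.approx(
            math.pi * EARTH_RADIUS_KM, abs=0.1)

    def test_quarter_meridian(self):
        assert great_circle_distance((0, 0), (0, 90)) == pytest.approx(
            math.pi * EARTH_RADIUS_KM / 2, abs=0.1)

    def test_matrix_matches_scalar(self, rng):
        pts = rng.uniform([-180, -60], [180, 60], size=(6, 2))
        D = pairwise_distances(pts)
        for i, j in itertools.combinations(range(6), 2):
            assert D[i, j] == pytest.approx(
                great_circle_distance(pts[i], pts[j]), rel=1e-9)


class TestInverseDistanceWeights:
    def test_two_regions_row_standardized(self):
        W = inverse_distance_weights([(0, 0), (10, 0)])
        assert np.allclose(W.w, [[0, 1], [1, 0]])

    def test_three_collinear_points(self):
        # equator degrees -> distances proportional to 1, 3, 2
        W = inverse_distance_weights([(0, 0), (1, 0), (3, 0)])
        raw0 = W.raw[0] / W.raw[0, 1]
        assert raw0 == pytest.approx([0.0, 1.0, 1 / 3], rel=1e-6)
        assert W.w[0] == pytest.approx([0.0, 0.75, 0.25], rel=1e-6)

    def test_raw_symmetric(self, rng):
        pts = rng.uniform([70, 20], [130, 50], size=(12, 2))
        W = inverse_distance_weights(pts)
        assert np.allclose(W.raw, W.raw.T)
        assert np.all(np.diag(W.raw) == 0)
        assert np.all(W.neighbor_counts == 11)

    def test_row_sums_one(self, rng):
        pts = rng.uniform([70, 20], [130, 50], size=(9, 2))
        W = inverse_distance_weights(pts)
        assert np.allclose(W.w.sum(axis=1), 1.0, atol=1e-12)

    def test_coincident_centroids_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            inverse_distance_weights([(0, 0), (0, 0), (1, 1)])

    def test_cutoff_zeroes_far_pairs(self):
        W = inverse_distance_weights([(0, 0), (1, 0), (50, 0)],
                                     cutoff_km=1000)
        assert W.raw[0, 2] == 0 and W.raw[0, 1] > 0

    def test_csv_round_trip(self, tmp_path, rng):
        pts = rng.uniform([70, 20], [130, 50], size=(5, 2))
        W = inverse_distance_weights(pts, region_ids=list("abcde"))
        p = tmp_path / "w.csv"
        W.to_dense_csv(p)
        W2 = WeightMatrix.from_dense_csv(p)
        assert np.allclose(W.raw, W2.raw)


def _moran_oracle(values, w):
    """Brute-force Moran's I via the double sum."""
    z = np.asarray(values, float) - np.mean(values)
    n = len(z)
    num = sum(w[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return n / w.sum() * num / (z @ z)


class TestMoransI:
    def test_n2_is_minus_one(self):
        W = inverse_distance_weights([(0, 0), (10, 0)])
        res = morans_i([1.0, 5.0], W, n_permutations=99, seed=1)
        assert res.I == pytest.approx(-1.0)
        assert res.expected_I == -1.0

    def test_alternating_ring(self):
        # 4-cycle with equal weights; alternating values are perfectly
        # negatively autocorrelated
        raw = np.array([[0, 1, 0, 1],
                        [1, 0, 1, 0],
                        [0, 1, 0, 1],
                        [1, 0, 1, 0]], dtype=float)
        W = WeightMatrix(raw)
        res = morans_i([1, -1, 1, -1], W, n_permutations=23, seed=0)
        assert res.I == pytest.approx(-1.0)

    def test_statistic_matches_oracle(self, rng):
        pts = rng.uniform([70, 20], [130, 50], size=(8, 2))
        W = inverse_distance_weights(pts)
        x = rng.normal(size=8)
        res = morans_i(x, W, n_permutations=9, seed=0)
        assert res.I == pytest.approx(_moran_oracle(x, W.w), rel=1e-10)

    @pytest.mark.parametrize("n", [5, 6])
    def test_exhaustive_p_matches_enumeration(self, n, rng):
        pts = rng.uniform([70, 20], [130, 50], size=(n, 2))
        W = inverse_distance_weights(pts)
        x = rng.normal(size=n)
        res = morans_i(x, W, exhaustive=True)
        w = W.w
        i_all = [_moran_oracle(x[list(p)], w)
                 for p in itertools.permutations(range(n))]
        expected_p = np.mean([i >= res.I - 1e-12 for i in i_all])
        assert res.p_value == pytest.approx(expected_p, abs=1e-12)
        # mean of I over all permutations is -1/(n-1)
        assert np.mean(i_all) == pytest.approx(-1 / (n - 1), rel=1e-8)

    def test_affine_invariance(self, rng):
        pts = rng.uniform([70, 20], [130, 50], size=(10, 2))
        W = inverse_distance_weights(pts)
        x = rng.normal(size=10)
        i1 = morans_i(x, W, n_permutations=9, seed=0).I
        i2 = morans_i(3.0 * x + 7.0, W, n_permutations=9, seed=0).I
        assert i1 == pytest.approx(i2, rel=1e-10)

    def test_permutation_p_in_unit_interval(self, rng):
        pts = rng.uniform([70, 20], [130, 50], size=(12, 2))
        W = inverse_distance_weights(pts)
        res = morans_i(rng.normal(size=12), W, n_permutations=199, seed=3)
        assert 0 < res.p_value <= 1
        assert res.n_permutations == 199

    def test_constant_values_rejected(self):
        W = inverse_distance_weights([(0, 0), (1, 0), (2, 0)])
        with pytest.raises(ValueError, match="constant"):
            morans_i([2.0, 2.0, 2.0], W, n_permutations=9)

    def test_seed_reproducibility(self, rng):
        pts = rng.uniform([70, 20], [130, 50], size=(15, 2))
        W = inverse_distance_weights(pts)
        x = rng.normal(size=15)
        a = morans_i(x, W, n_permutations=499, seed=11)
        b = morans_i(x, W, n_permutations=499, seed=11)
        assert a.p_value == b.p_value
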