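"""Inverse-distance spatial weights and Global Moran's I.

Spatial dependence between regions is encoded as an inverse-distance weight
matrix over great-circle distances between region centroids. Global Moran's I
over these weights, with a permutation null, decides whether a spatially
structured (CAR) random effect is warranted in the regression model.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_KM",
    "WeightMatrix",
    "MoranResult",
    "great_circle_distance",
    "pairwise_distances",
    "inverse_distance_weights",
    "morans_i",
    "morans_i_residuals",
]

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


def great_circle_distance(a, b) -> float:
    """Haversine distance in km between (lon, lat) points in decimal degrees."""
    lon1, lat1 = math.radians(a[0]), math.radians(a[1])
    lon2, lat2 = math.radians(b[0]), math.radians(b[1])
    s = (math.sin((lat2 - lat1) / 2) ** 2
         + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2) ** 2)
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(s)))


def pairwise_distances(centroids: np.ndarray) -> np.ndarray:
    """Symmetric n x n great-circle distance matrix from (n, 2) lon/lat."""
    c = np.asarray(centroids, dtype=float)
    lon = np.radians(c[:, 0])[:, None]
    lat = np.radians(c[:, 1])[:, None]
    s = (np.sin((lat.T - lat) / 2) ** 2
         + np.cos(lat) * np.cos(lat.T) * np.sin((lon.T - lon) / 2) ** 2)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class WeightMatrix:
    """Spatial weights with both raw (symmetric) and row-standardized forms.

    ``raw`` keeps the symmetric inverse-distance weights needed to build the
    CAR precision matrix; ``w`` is the row-standardized form (each row with at
    least one neighbour sums to 1) used by Moran's I and the CAR conditional
    mean.
    """

    raw: np.ndarray
    region_ids: np.ndarray | None = None
    row_standardized: bool = True

    def __post_init__(self):
        raw = np.asarray(self.raw, dtype=float)
        if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
            raise ValueError("weight matrix must be square")
        if np.any(np.diag(raw) != 0):
            raise ValueError("weight matrix diagonal must be zero")
        if not np.allclose(raw, raw.T, atol=1e-10):
            raise ValueError("raw weight matrix must be symmetric")
        if np.any(raw < 0):
            raise ValueError("weights must be non-negative")
        self.raw = raw

    @property
    def n(self) -> int:
        return self.raw.shape[0]

    @property
    def neighbor_counts(self) -> np.ndarray:
        return (self.raw > 0).sum(axis=1)

    @property
    def w(self) -> np.ndarray:
        """The matrix in its declared form (row-standardized or raw)."""
        if not self.row_standardized:
            return self.raw
        rowsum = self.raw.sum(axis=1, keepdims=True)
        safe = np.where(rowsum > 0, rowsum, 1.0)
        return self.raw / safe

    def to_dense_csv(self, path):
        ids = self.region_ids if self.region_ids is not None else np.arange(self.n)
        pd.DataFrame(self.raw, index=ids, columns=ids).to_csv(path)

    def to_triplet_csv(self, path):
        i, j = np.nonzero(self.raw)
        pd.DataFrame({"i": i, "j": j, "w": self.raw[i, j]}).to_csv(path, index=False)

    @classmethod
    def from_dense_csv(cls, path, row_standardized=True):
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), region_ids=df.index.to_numpy(),
                   row_standardized=row_standardized)


def inverse_distance_weights(centroids, region_ids=None, row_standardize=True,
                             cutoff_km=None) -> WeightMatrix:
    """Inverse great-circle-distance weights between region centroids.

    Raw weights are w_ij = 1/d_ij (km) off-diagonal; with no distance
    cut-off every pair is a neighbour. An optional ``cutoff_km`` zeroes
    weights beyond that distance.
    """
    c = np.asarray(centroids, dtype=float)
    n = c.shape[0]
    if n < 2:
        raise ValueError("need at least two regions")
    d = pairwise_distances(c)
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0):
        i, j = np.argwhere((d == 0) & off)[0]
        raise ValueError(f"coincident centroids for regions {i} and {j}")
    raw = np.zeros_like(d)
    raw[off] = 1.0 / d[off]
    if cutoff_km is not None:
        raw[d > cutoff_km] = 0.0
    return WeightMatrix(raw, region_ids=None if region_ids is None
                        else np.asarray(region_ids),
                        row_standardized=row_standardize)


@dataclass
class MoranResult:
    I: float
    expected_I: float
    p_value: float
    n_permutations: int
    seed: int | None
    alternative: str
    exhaustive: bool = False

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def _moran_statistic(z: np.ndarray, w: np.ndarray) -> float:
    n = z.size
    s0 = w.sum()
    return float(n / s0 * (z @ w @ z) / (z @ z))


def morans_i(values, W: WeightMatrix, n_permutations: int = 9999,
             seed: int | None = None, alternative: str = "greater",
             exhaustive: bool = False) -> MoranResult:
    """Global Moran's I with a permutation null.

    I = (n/S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z the centred values
    and S0 the total weight. The null distribution comes from random
    relabellings of the values over the spatial units; the reported p-value
    uses the add-one rule p = (1 + #{I_perm >= I_obs}) / (1 + B) so it is
    never exactly zero. With ``exhaustive=True`` all n! assignments are
    enumerated instead (n <= 8) and p is the exact fraction.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size != W.n:
        raise ValueError("values must be a vector of length W.n")
    if np.ptp(x) == 0:
        raise ValueError("Moran's I is undefined for constant values")
    if alternative not in ("greater", "two_sided"):
        raise ValueError("alternative must be 'greater' or 'two_sided'")
    w = W.w
    n = x.size
    z = x - x.mean()
    i_obs = _moran_statistic(z, w)
    expected = -1.0 / (n - 1)

    def extremity(i_perm):
        if alternative == "greater":
            return i_perm >= i_obs - 1e-12
        return abs(i_perm - expected) >= abs(i_obs - expected) - 1e-12

    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if extremity(_moran_statistic(z[list(perm)], w)):
                count += 1
        return MoranResult(i_obs, expected, count / total, total, seed,
                           alternative, exhaustive=True)

    rng = np.random.default_rng(seed)
    # vectorised permutation null: rows of Z are permuted copies of z
    perm_idx = np.argsort(rng.random((n_permutations, n)), axis=1)
    Z = z[perm_idx]
    s0 = w.sum()
    cross = np.einsum("bi,ij,bj->b", Z, w, Z)
    i_perm = n / s0 * cross / (z @ z)
    count = int(np.count_nonzero(extremity(i_perm)))
    p = (1 + count) / (1 + n_permutations)
    return MoranResult(i_obs, expected, float(p), n_permutations, seed,
                       alternative)


def morans_i_residuals(y, X, W: WeightMatrix, n_permutations: int = 9999,
                       seed: int | None = None,
                       alternative: str = "greater") -> MoranResult:
    """Moran's I of least-squares residuals with a Freedman-Lane null.

    Residuals of a fitted regression are slightly negatively correlated by
    construction, so naively permuting them makes the Moran test
    conservative. Here each permuted residual vector is re-projected
    through the residual-maker matrix M = I - Z(Z'Z)^{-1}Z' before the
    statistic is evaluated, which restores the test's nominal size. X may
    be empty (intercept-only: plain centring).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    X = np.asarray(X, dtype=float).reshape(n, -1)
    Z = np.column_stack([np.ones(n), X])
    M = np.eye(n) - Z @ np.linalg.solve(Z.T @ Z, Z.T)
    e = M @ y
    if np.ptp(e) == 0:
        raise ValueError("residuals are constant; Moran's I undefined")
    if alternative not in ("greater", "two_sided"):
        raise ValueError("alternative must be 'greater' or 'two_sided'")
    w = W.w
    z = e - e.mean()
    i_obs = _moran_statistic(z, w)
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    perm_idx = np.argsort(rng.random((n_permutations, n)), axis=1)
    E = e[perm_idx] @ M.T
    E = E - E.mean(axis=1, keepdims=True)
    s0 = w.sum()
    i_perm = (n / s0) * np.einsum("bi,ij,bj->b", E, w, E) / (E ** 2).sum(axis=1)
    if alternative == "greater":
        count = int(np.count_nonzero(i_perm >= i_obs - 1e-12))
    else:
        count = int(np.count_nonzero(
            np.abs(i_perm - expected) >= abs(i_obs - expected) - 1e-12))
    p = (1 + count) / (1 + n_permutations)
    return MoranResult(i_obs, expected, float(p), n_permutations, seed,
                       alternative)
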