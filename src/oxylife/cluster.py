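"""Hierarchical clustering of cause-of-death YLL profiles.

Regions are clustered on their age-standardized years-of-life-lost (YLL)
profiles over the top causes of death, using Euclidean distance and Ward's
minimum-variance criterion (Lance-Williams recurrence, heights in the
sqrt(2 * ESS-increase) convention shared by the common implementations).
Cutting the tree at k clusters yields subgroups whose per-cause YLLs and
oxygen levels are then compared: one-way ANOVA with pairwise t tests when
every group passes Shapiro-Wilk normality and Levene homogeneity, else
Kruskal-Wallis with pairwise Wilcoxon rank-sum tests; all pairwise p-values
are Bonferroni-adjusted.

Ward linkage and the Kruskal-Wallis statistic are implemented here (scipy's
versions act only as oracles in the tests); the routine normality,
homogeneity, ANOVA and t tests delegate to scipy.stats.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .hypoxia import mann_whitney_u

__all__ = [
    "YLLMatrix",
    "ClusterResult",
    "ClusterTest",
    "ward_cluster",
    "kruskal_wallis",
    "compare_clusters",
    "export_dendrogram",
    "cut_tree",
]


@dataclass
class YLLMatrix:
    """Regions x causes matrix of age-standardized YLLs per 100,000."""

    values: pd.DataFrame  # index = region ids, columns = cause names

    def __post_init__(self):
        df = self.values
        if df.isna().any().any():
            raise ValueError("YLL matrix must have no missing cells")
        if (df.to_numpy() < 0).any():
            raise ValueError("YLL values must be non-negative")

    @classmethod
    def from_csv(cls, path):
        return cls(pd.read_csv(path, index_col=0))

    def to_csv(self, path):
        self.values.to_csv(path)

    @property
    def regions(self):
        return self.values.index.to_numpy()

    @property
    def causes(self):
        return self.values.columns.to_numpy()


@dataclass
class ClusterResult:
    """Ward merge tree and a k-cut labelling.

    ``linkage`` follows the familiar (n-1, 4) layout: indices of the two
    merged nodes (leaves are 0..n-1, internal nodes n..2n-2 in merge order),
    merge height, and size of the new cluster.
    """

    linkage: np.ndarray
    labels: pd.Series            # region id -> cluster id in 1..k
    k: int
    region_ids: np.ndarray = field(default=None)

    @property
    def n(self) -> int:
        return self.linkage.shape[0] + 1


def ward_cluster(Y, k: int = 3, standardize: bool = False) -> ClusterResult:
    """Agglomerative Ward clustering of YLL rows, cut at k clusters.

    Rows are clustered on their raw scale by default (the subgroups in this
    analysis separate on absolute YLL levels); ``standardize`` z-scores each
    cause first. Merge heights are produced by the Lance-Williams update
    d(k, i+j)^2 = ((n_i+n_k) d_ki^2 + (n_j+n_k) d_kj^2 - n_k d_ij^2) /
    (n_i+n_j+n_k) starting from Euclidean distances, which makes
    height^2 / 2 the increase in within-cluster error sum of squares at each
    merge. Ties break on the smallest node indices.
    """
    df = Y.values if isinstance(Y, YLLMatrix) else pd.DataFrame(Y)
    X = df.to_numpy(dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd

    # squared-distance matrix between active nodes
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    sizes = {i: 1 for i in range(n)}
    active = dict(enumerate(range(n)))   # row index in d2 -> node id
    link = np.zeros((n - 1, 4))

    row_ids = list(range(n))             # active row positions
    for step in range(n - 1):
        # find the closest active pair, smallest indices on ties
        best = None
        for ai, bi in itertools.combinations(row_ids, 2):
            v = d2[ai, bi]
            if best is None or v < best[0] - 1e-15:
                best = (v, ai, bi)
        v, ai, bi = best
        na, nb = sizes[active[ai]], sizes[active[bi]]
        new_id = n + step
        link[step] = [min(active[ai], active[bi]),
                      max(active[ai], active[bi]), np.sqrt(v), na + nb]
        # Lance-Williams update into row ai
        for ci in row_ids:
            if ci in (ai, bi):
                continue
            nc = sizes[active[ci]]
            upd = ((na + nc) * d2[ai, ci] + (nb + nc) * d2[bi, ci]
                   - nc * v) / (na + nb + nc)
            d2[ai, ci] = d2[ci, ai] = upd
        row_ids.remove(bi)
        sizes[new_id] = na + nb
        active[ai] = new_id

    region_ids = df.index.to_numpy()
    labels = cut_tree(link, k, region_ids)
    return ClusterResult(link, labels, k, region_ids)


def cut_tree(linkage: np.ndarray, k: int, region_ids=None) -> pd.Series:
    """Labels in 1..k from the first n-k merges of a linkage matrix.

    Clusters are numbered by order of first appearance along the rows.
    """
    n = linkage.shape[0] + 1
    if region_ids is None:
        region_ids = np.arange(n)
    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b = int(linkage[step, 0]), int(linkage[step, 1])
        new = n + step
        parent[find(a)] = new
        parent[find(b)] = new
    roots = {}
    lab = np.empty(n, dtype=int)
    for i in range(n):
        r = find(i)
        roots.setdefault(r, len(roots) + 1)
        lab[i] = roots[r]
    return pd.Series(lab, index=region_ids, name="cluster")


def kruskal_wallis(groups, exact_limit: int = 8):
    """Kruskal-Wallis H with tie correction; exact p for small samples.

    H = 12/(N(N+1)) * sum_g n_g (Rbar_g - (N+1)/2)^2, divided by the tie
    correction 1 - sum(t^3 - t)/(N^3 - N). The null is exact (enumeration
    over all distinct assignments of the pooled values to the group sizes)
    when N <= exact_limit, otherwise chi-square with g-1 df.
    Returns (H, p, method).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    sizes = [g.size for g in groups]
    pooled = np.concatenate(groups)
    N = pooled.size

    def h_stat(pooled_vals, sizes):
        ranks = stats.rankdata(pooled_vals)
        h = 0.0
        start = 0
        for ng in sizes:
            rbar = ranks[start:start + ng].mean()
            h += ng * (rbar - (N + 1) / 2.0) ** 2
            start += ng
        h *= 12.0 / (N * (N + 1))
        _, t = np.unique(pooled_vals, return_counts=True)
        corr = 1.0 - (t ** 3 - t).sum() / (N ** 3 - N)
        if corr == 0:
            raise ValueError("all values identical")
        return h / corr

    h_obs = h_stat(pooled, sizes)
    if N <= exact_limit:
        # enumerate which pooled positions go to each group
        count = 0
        total = 0
        idx = list(range(N))
        for combo in _group_assignments(idx, sizes):
            perm = np.concatenate([pooled[list(c)] for c in combo])
            total += 1
            if h_stat(perm, sizes) >= h_obs - 1e-12:
                count += 1
        return float(h_obs), count / total, "exact"
    p = float(stats.chi2.sf(h_obs, len(sizes) - 1))
    return float(h_obs), p, "chisq"


def _group_assignments(idx, sizes):
    """All ways to partition idx into ordered groups of the given sizes."""
    if len(sizes) == 1:
        yield (tuple(idx),)
        return
    first, rest = sizes[0], sizes[1:]
    for combo in itertools.combinations(idx, first):
        remaining = [i for i in idx if i not in combo]
        for tail in _group_assignments(remaining, rest):
            yield (combo,) + tail


@dataclass
class ClusterTest:
    """Omnibus and pairwise comparison of one variable across clusters."""

    cause: str
    route: str                 # 'anova' or 'kruskal'
    statistic: float           # F or H
    p_value: float
    pairwise: dict             # (cluster_a, cluster_b) -> Bonferroni-adjusted p
    group_summaries: dict      # cluster -> formatted summary


def _anova_prerequisites(groups, alpha=0.05) -> bool:
    """Per-group Shapiro-Wilk normality AND Levene (median-centred)
    homogeneity, all at *alpha*; groups below size 3 fail the check."""
    for g in groups:
        if g.size < 3 or np.ptp(g) == 0:
            return False
        if stats.shapiro(g).pvalue <= alpha:
            return False
    return stats.levene(*groups, center="median").pvalue > alpha


def compare_clusters(Y, labels: pd.Series, alpha: float = 0.05,
                     oxygen: pd.Series | None = None) -> list:
    """Between-cluster tests for every cause (and optionally oxygen).

    Per variable: when the ANOVA prerequisites hold, one-way ANOVA with
    pairwise two-sample t tests; otherwise Kruskal-Wallis with pairwise
    Wilcoxon rank-sum tests. Pairwise p-values are multiplied by the number
    of pairs (Bonferroni), capped at 1. Clusters of size 1 are excluded from
    pairwise testing with a warning.
    """
    from .hypoxia import describe

    df = Y.values if isinstance(Y, YLLMatrix) else pd.DataFrame(Y)
    variables = {str(c): df[c] for c in df.columns}
    if oxygen is not None:
        variables = {"oxygen": oxygen, **variables}
    cluster_ids = sorted(labels.unique())
    if len(cluster_ids) < 2:
        raise ValueError("need at least two clusters")
    results = []
    for name, series in variables.items():
        groups = {c: series[labels.index[labels == c]].dropna().to_numpy()
                  for c in cluster_ids}
        testable = {c: g for c, g in groups.items() if g.size >= 2}
        skipped = [c for c in cluster_ids if c not in testable]
        if skipped:
            warnings.warn(f"{name}: cluster(s) {skipped} of size < 2 "
                          "excluded from testing", stacklevel=2)
        if len(testable) < 2:
            continue
        glist = list(testable.values())
        keys = list(testable.keys())
        pairs = list(itertools.combinations(keys, 2))
        m = len(pairs)
        if _anova_prerequisites(glist, alpha):
            route = "anova"
            stat, p = stats.f_oneway(*glist)
            pairwise = {}
            for a, b in pairs:
                raw = stats.ttest_ind(testable[a], testable[b]).pvalue
                pairwise[(a, b)] = min(1.0, float(raw) * m)
        else:
            route = "kruskal"
            stat, p, _ = kruskal_wallis(glist, exact_limit=0)
            pairwise = {}
            for a, b in pairs:
                raw = mann_whitney_u(testable[a], testable[b]).p_value
                pairwise[(a, b)] = min(1.0, raw * m)
        summaries = {c: describe(g).formatted for c, g in testable.items()}
        results.append(ClusterTest(name, route, float(stat), float(p),
                                   pairwise, summaries))
    return results


def cluster_tests_table(tests) -> pd.DataFrame:
    """Flatten ClusterTest objects into a comparison table."""
    rows = []
    for t in tests:
        row = {"cause": t.cause, "route": t.route, "statistic": t.statistic,
               "p_value": t.p_value}
        for c, s in t.group_summaries.items():
            row[f"cluster_{c}"] = s
        for (a, b), p in t.pairwise.items():
            row[f"p_adj_{a}_vs_{b}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def export_dendrogram(result: ClusterResult, leaf_names=None):
    """Newick string for the merge tree (plus a linkage DataFrame).

    Branch lengths are half the height difference between a node and its
    parent, so two leaves merging at height h read ``(A:h/2,B:h/2);``.
    """
    link = result.linkage
    n = link.shape[0] + 1
    if leaf_names is None:
        leaf_names = (result.region_ids if result.region_ids is not None
                      else [f"L{i}" for i in range(n)])
    heights = {i: 0.0 for i in range(n)}
    children = {}
    for step in range(n - 1):
        a, b, h = int(link[step, 0]), int(link[step, 1]), link[step, 2]
        node = n + step
        heights[node] = h
        children[node] = (a, b)

    def newick(node):
        if node < n:
            return str(leaf_names[node])
        a, b = children[node]
        ba = (heights[node] - heights[a]) / 2.0
        bb = (heights[node] - heights[b]) / 2.0
        return f"({newick(a)}:{ba:.6g},{newick(b)}:{bb:.6g})"

    root = 2 * n - 2
    nwk = newick(root) + ";"
    linkage_df = pd.DataFrame(link, columns=["left", "right", "height", "size"])
    return nwk, linkage_df
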