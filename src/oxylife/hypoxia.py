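"""Hypoxia dichotomy and group comparison (descriptive stage).

Regions are split at an ambient oxygen partial pressure of 140 mmHg — the
level reached around 1500 m of altitude, conventionally taken as the onset
of physiologically relevant hypoxia. Each variable is summarised per group
(mean +/- SD when a Shapiro-Wilk test accepts normality, otherwise median
and quartiles) and the groups are compared with the Mann-Whitney U test.

The U test here is hand-rolled with an exact small-sample null (a counting
recurrence over rank configurations) because complete-separation U values
are part of the reported output; scipy's version serves as an independent
oracle in the test-suite only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HYPOXIA_CUTOFF_MMHG",
    "MannWhitneyResult",
    "Summary",
    "GroupComparison",
    "split_by_oxygen",
    "mann_whitney_u",
    "describe",
    "compare_groups",
]

HYPOXIA_CUTOFF_MMHG = 140.0


def split_by_oxygen(regions, cutoff: float = HYPOXIA_CUTOFF_MMHG):
    """Split a region table into (high, low) oxygen groups at *cutoff*.

    Group A is oxygen >= cutoff (a value of exactly 140 counts as
    high-oxygen), group B is oxygen < cutoff. Either group may be empty;
    downstream comparisons are then skipped with a warning.
    """
    df = regions.df if hasattr(regions, "df") else regions
    if df["oxygen"].isna().any():
        raise ValueError("oxygen must be present for every region")
    high = df[df["oxygen"] >= cutoff].reset_index(drop=True)
    low = df[df["oxygen"] < cutoff].reset_index(drop=True)
    if len(high) == 0 or len(low) == 0:
        warnings.warn("one oxygen group is empty; comparisons will be skipped",
                      stacklevel=2)
    return high, low


@dataclass
class MannWhitneyResult:
    u_a: float          # #{a > b} + half-ties
    u_b: float          # n_a * n_b - u_a
    p_value: float
    n_a: int
    n_b: int
    method: str         # 'exact' or 'normal'


def _exact_u_counts(m: int, n: int) -> np.ndarray:
    """Null distribution of U for group sizes (m, n) without ties.

    counts[u] = number of rank configurations giving Mann-Whitney statistic
    u, via the standard recurrence f(m, n, u) = f(m-1, n, u-n) + f(m, n-1, u).
    """
    # dp[j, u] = count for group sizes (i, j) while iterating i = 0..m
    max_u = m * n
    dp = np.zeros((n + 1, max_u + 1), dtype=float)
    dp[:, 0] = 1.0
    for _i in range(1, m + 1):
        new = np.zeros_like(dp)
        new[0, 0] = 1.0
        for j in range(1, n + 1):
            new[j] = new[j - 1]
            new[j, j:] += dp[j, :max_u + 1 - j]
        dp = new
    return dp[n]


def mann_whitney_u(a, b, method: str = "auto") -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    U_a counts pairs where an a-value exceeds a b-value (ties count half);
    U_b = n_a n_b - U_a. The p-value is exact (enumeration of the rank null)
    when n_a + n_b <= 20 with no ties, otherwise a normal approximation with
    tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    m, n = a.size, b.size
    diff = a[:, None] - b[None, :]
    u_a = float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))
    u_b = m * n - u_a
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size

    if method == "auto":
        method = "exact" if (m + n <= 20 and not has_ties) else "normal"
    if method == "exact":
        if has_ties:
            raise ValueError("exact p-value undefined with ties")
        counts = _exact_u_counts(m, n)
        total = counts.sum()
        u_min = min(u_a, u_b)
        p = 2.0 * counts[: int(u_min) + 1].sum() / total
        p = min(1.0, p)
    elif method == "normal":
        mu = m * n / 2.0
        N = m + n
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (N * (N - 1))
        var = m * n / 12.0 * ((N + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u_a - mu) - 0.5) / np.sqrt(var)
            z = max(z, 0.0)
            p = 2.0 * stats.norm.sf(z)
            p = min(1.0, p)
    else:
        raise ValueError("method must be 'auto', 'exact' or 'normal'")
    return MannWhitneyResult(u_a, u_b, float(p), m, n, method)


@dataclass
class Summary:
    n: int
    route: str                # 'normal', 'nonnormal' or 'raw'
    mean: float
    sd: float
    median: float
    q25: float
    q75: float
    shapiro_p: float

    @property
    def formatted(self) -> str:
        if self.route == "normal":
            return f"{self.mean:.2f} ± {self.sd:.2f}"
        if self.route == "nonnormal":
            return f"{self.median:.2f} ({self.q25:.2f}–{self.q75:.2f})"
        return f"raw (n={self.n})"


def describe(values, alpha: float = 0.05) -> Summary:
    """Normality-routed summary of a continuous variable.

    Shapiro-Wilk at *alpha* decides between mean +/- SD (sample SD, n-1
    denominator) and median with quartiles (linear interpolation, the
    type-7 convention). Fewer than 3 values: no test, raw echo.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    mean = float(x.mean()) if n else np.nan
    sd = float(x.std(ddof=1)) if n > 1 else np.nan
    med, q25, q75 = (np.nan,) * 3
    if n:
        med = float(np.median(x))
        q25, q75 = (float(q) for q in np.percentile(x, [25, 75]))
    if n < 3:
        return Summary(n, "raw", mean, sd, med, q25, q75, np.nan)
    if np.ptp(x) == 0:
        return Summary(n, "nonnormal", mean, 0.0, med, q25, q75, np.nan)
    shapiro_p = float(stats.shapiro(x).pvalue)
    route = "normal" if shapiro_p > alpha else "nonnormal"
    return Summary(n, route, mean, sd, med, q25, q75, shapiro_p)


@dataclass
class GroupComparison:
    variable: str
    summary_a: Summary
    summary_b: Summary
    u_a: float
    u_b: float
    p_value: float
    n_a: int
    n_b: int


def compare_groups(regions, variables=None,
                   cutoff: float = HYPOXIA_CUTOFF_MMHG) -> pd.DataFrame:
    """Per-variable comparison of the high- vs low-oxygen groups.

    Returns one row per variable with both group summaries, both U
    orientations and the two-sided p-value — the layout of a descriptive
    comparison table. If either group is empty the table is empty.
    """
    df = regions.df if hasattr(regions, "df") else regions
    high, low = split_by_oxygen(df, cutoff)
    if variables is None:
        variables = [c for c in df.columns
                     if c not in ("region_id", "name", "level", "lon", "lat")
                     and pd.api.types.is_numeric_dtype(df[c])]
    rows = []
    if len(high) == 0 or len(low) == 0:
        return pd.DataFrame(rows)
    for var in variables:
        a = high[var].dropna().to_numpy()
        b = low[var].dropna().to_numpy()
        if a.size == 0 or b.size == 0:
            continue
        mw = mann_whitney_u(a, b)
        rows.append({
            "variable": var,
            "group_high": describe(a).formatted,
            "group_low": describe(b).formatted,
            "U_high": mw.u_a, "U_low": mw.u_b,
            "p_value": mw.p_value, "n_high": mw.n_a, "n_low": mw.n_b,
        })
    return pd.DataFrame(rows)
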