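"""Calibration and recovery studies on the synthetic generator.

These are the simulation experiments that validate the pipeline end to end:
complete-separation Mann-Whitney statistics of the oxygen dichotomy,
parameter recovery and interval coverage of the CAR sampler, size and power
of the Moran model gate, behaviour of the DIC screening rules, planted-
cluster recovery of the Ward stage, and the type-I error of the
between-cluster testing stack. Every study is a pure function of its seed.

Study sizes default to what a single CPU handles in minutes; they are
arguments, not constants.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bayes, cluster, hypoxia, screening, spatial
from .synthetic import SyntheticConfig, generate_regions, generate_yll

__all__ = [
    "complete_separation_u",
    "recovery_study",
    "moran_gate_study",
    "collinear_drop_study",
    "stepwise_study",
    "ward_recovery_study",
    "cluster_test_type1_study",
    "adjusted_rand_index",
]

#: the generator's "sigma_u large" regime used by gate-power studies
SIGMA_U_LARGE = 6.0


def _fast_spec(seed, model="iid", n_iter=2500, n_burnin=800, n_chains=1):
    return bayes.ModelSpec(model=model, seed=seed, n_chains=n_chains,
                           n_iter=n_iter, n_burnin=n_burnin)


def _model_frame(rt):
    df = rt.df.copy()
    g = df["gdp_per_capita"]
    df["gdp_per_capita"] = (g - g.mean()) / g.std(ddof=1)
    y = df["life_expectancy"].to_numpy(dtype=float)
    X = df[["oxygen", "gdp_per_capita", "health_tech_per_1000"]].to_numpy()
    return df, y, X


def complete_separation_u(n_regions, n_low, seed):
    """Oxygen-row U statistics of the 140 mmHg comparison table.

    The split variable compared against its own cut-off is completely
    separated by construction, forcing the two U orientations to 0 and
    n_high * n_low exactly. Returns (u_high, u_low, n_high, n_low).
    """
    k = n_low
    a = (n_regions - k) // 2
    cfg = SyntheticConfig(n_regions=n_regions, n_low_oxygen=n_low,
                          cluster_sizes=(a, n_regions - k - a, k))
    rt, _, _ = generate_regions(cfg, seed)
    table = hypoxia.compare_groups(rt, ["oxygen"])
    row = table[table["variable"] == "oxygen"].iloc[0]
    return (float(row["U_high"]), float(row["U_low"]),
            int(row["n_high"]), int(row["n_low"]))


def recovery_study(n_reps=100, seed=0, n_regions=40, beta_oxygen=0.15,
                   sigma_u=1.0, sigma_v=0.5, n_iter=2000, n_burnin=500,
                   n_chains=2):
    """Bias and 95%-interval coverage of the oxygen slope under the CAR fit.

    Each replicate generates a fresh map and outcome from the CAR law and
    refits with the generator's own weight graph. Returns a dict with the
    mean posterior-mean bias, the mean posterior SD, their ratio, and the
    credible-interval coverage.
    """
    k = 6
    a = (n_regions - k) // 2
    cfg = SyntheticConfig(n_regions=n_regions, n_low_oxygen=k,
                          cluster_sizes=(a, n_regions - k - a, k),
                          sigma_u=sigma_u, sigma_v=sigma_v,
                          beta_true={"oxygen": beta_oxygen,
                                     "gdp_per_capita": 0.877,
                                     "health_tech_per_1000": 0.752})
    errs, sds, hits = [], [], 0
    for r in range(n_reps):
        rt, W, _ = generate_regions(cfg, seed * 100003 + r)
        _, y, X = _model_frame(rt)
        spec = bayes.ModelSpec(model="car", n_chains=n_chains, n_iter=n_iter,
                               n_burnin=n_burnin, seed=seed + r)
        fit = bayes.fit_car(y, X, W, spec)
        row = fit.summaries.loc["beta[x0]"]
        errs.append(row["mean"] - beta_oxygen)
        sds.append(row["sd"])
        hits += row["q2.5"] <= beta_oxygen <= row["q97.5"]
    bias = float(np.mean(errs))
    mean_sd = float(np.mean(sds))
    return {"bias": bias, "mean_posterior_sd": mean_sd,
            "bias_in_posterior_sds": bias / mean_sd,
            "coverage": hits / n_reps, "n_reps": n_reps}


def _gate_p_value(seed, sigma_u, n_permutations=999):
    """Freedman-Lane Moran p on fixed-effects residuals (the gate input)."""
    cfg = SyntheticConfig(sigma_u=sigma_u, sigma_v=0.5)
    rt, _, _ = generate_regions(cfg, seed)
    _, y, X = _model_frame(rt)
    W = spatial.inverse_distance_weights(rt.centroids())
    return spatial.morans_i_residuals(y, X, W,
                                      n_permutations=n_permutations,
                                      seed=seed).p_value


def moran_gate_study(n_null=1000, n_power=200, seed=0, alpha=0.05,
                     sigma_u_large=SIGMA_U_LARGE):
    """Size (sigma_u = 0) and power (sigma_u large) of the model gate."""
    null_rej = np.mean([_gate_p_value(seed * 7919 + s, 0.0) < alpha
                        for s in range(n_null)])
    power = np.mean([_gate_p_value(seed * 7919 + s, sigma_u_large) < alpha
                     for s in range(n_power)])
    return {"size": float(null_rej), "power": float(power),
            "n_null": n_null, "n_power": n_power,
            "sigma_u_large": sigma_u_large}


def collinear_drop_study(n_reps=100, seed=0, n=200, effect=10.0,
                         twin_noise_sd=0.1):
    """How often the DIC pair rule drops the non-causal collinear twin."""
    dropped_twin = 0
    for r in range(n_reps):
        rng = np.random.default_rng(seed * 99991 + r)
        x1 = rng.normal(size=n)
        x2 = x1 + rng.normal(0, twin_noise_sd, n)
        y = 1.0 + effect * x1 + rng.normal(0, 1.0, n)
        df = pd.DataFrame({"x1": x1, "x2": x2})
        rep = screening.correlation_filter(df, ["x1", "x2"], y,
                                           model_spec=_fast_spec(seed + r))
        dropped_twin += [d[0] for d in rep.dropped] == ["x2"]
    return {"drop_rate": dropped_twin / n_reps, "n_reps": n_reps}


def stepwise_study(n_reps=50, seed=0, n=200, effect=10.0, n_noise=3):
    """Backward-DIC stepwise: signal retention and noise shedding rates."""
    full_success = 0
    signal_kept = 0
    shed_events = 0
    for r in range(n_reps):
        rng = np.random.default_rng(seed * 60013 + r)
        cols = ["signal"] + [f"n{i}" for i in range(n_noise)]
        x = pd.DataFrame(rng.normal(size=(n, 1 + n_noise)), columns=cols)
        y = 1.0 + effect * x["signal"].to_numpy() + rng.normal(0, 1.0, n)
        rep = screening.stepwise_select(x, cols, y,
                                        model_spec=_fast_spec(seed + r))
        signal_kept += "signal" in rep.selected
        shed = n_noise - sum(c in rep.selected for c in cols[1:])
        shed_events += shed
        full_success += ("signal" in rep.selected) and shed == n_noise
    return {"signal_retention_rate": signal_kept / n_reps,
            "full_success_rate": full_success / n_reps,
            "noise_shed_event_rate": shed_events / (n_reps * n_noise),
            "n_reps": n_reps}


def adjusted_rand_index(a, b) -> float:
    """Adjusted Rand index between two labelings."""
    from scipy.special import comb

    ct = pd.crosstab(pd.Series(list(a)), pd.Series(list(b))).to_numpy()
    sum_comb = comb(ct, 2).sum()
    sum_a = comb(ct.sum(axis=1), 2).sum()
    sum_b = comb(ct.sum(axis=0), 2).sum()
    n = comb(ct.sum(), 2)
    exp = sum_a * sum_b / n
    max_idx = (sum_a + sum_b) / 2
    if max_idx == exp:
        return 1.0
    return float((sum_comb - exp) / (max_idx - exp))


def ward_recovery_study(n_seeds=100, seed=0, shift=5.0):
    """Fraction of seeds where the k=3 cut recovers planted labels exactly."""
    cfg = SyntheticConfig(between_cluster_shift=shift)
    perfect = 0
    for s in range(n_seeds):
        Y, labels, _ = generate_yll(cfg, seed * 31337 + s)
        res = cluster.ward_cluster(Y, k=3)
        ari = adjusted_rand_index(res.labels.reindex(labels.index), labels)
        perfect += ari == 1.0
    return {"perfect_recovery_rate": perfect / n_seeds, "n_seeds": n_seeds}


def cluster_test_type1_study(n_tables=1000, seed=0, n_causes=5,
                             sizes=(12, 16, 6), alpha=0.05):
    """Per-cause false-positive rate when all clusters share one law."""
    rng = np.random.default_rng(seed * 104729)
    n = sum(sizes)
    labels = pd.Series(np.repeat([1, 2, 3], sizes),
                       index=[f"r{i}" for i in range(n)])
    n_sig = 0
    n_tests = 0
    for _ in range(n_tables):
        X = pd.DataFrame(rng.normal(size=(n, n_causes)),
                         columns=[f"c{j}" for j in range(n_causes)],
                         index=labels.index)
        tests = cluster.compare_clusters(X, labels, alpha=alpha)
        for t in tests:
            n_tests += 1
            n_sig += t.p_value < alpha
    rate = n_sig / n_tests
    se = np.sqrt(alpha * (1 - alpha) / n_tests)
    return {"type1_rate": float(rate), "mc_se": float(se),
            "n_tests": n_tests}
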