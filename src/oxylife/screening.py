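"""Pre-modelling covariate screening.

Two stages run before the regression model is fitted:

1. Correlation filter — for every candidate pair whose Pearson |r| exceeds
   the threshold (default 0.7, strict), fit the two univariate Bayesian
   models and drop the member with the higher DIC. Pairs are processed in
   descending |r|; a variable already dropped is skipped.
2. Stepwise selection — backward elimination by DIC from the remaining set:
   at each step the removal that most decreases DIC is applied, until no
   removal decreases it. A forward mode is available.

Every candidate model gets a fixed seed derived from the base seed and its
covariate subset, so DIC comparisons are reproducible and the selected set
does not depend on candidate ordering (ties in DIC break lexicographically
on variable name and are logged in the report).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bayes
from .spatial import WeightMatrix

__all__ = ["ScreeningReport", "correlation_filter", "stepwise_select"]


@dataclass
class ScreeningReport:
    correlation_matrix: pd.DataFrame = None
    flagged_pairs: list = field(default_factory=list)   # (a, b, r)
    dropped: list = field(default_factory=list)         # (var, reason, dic)
    remaining: list = field(default_factory=list)
    stepwise_trace: list = field(default_factory=list)
    selected: list = field(default_factory=list)
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "correlation_matrix": (self.correlation_matrix.round(6).to_dict()
                                   if self.correlation_matrix is not None
                                   else None),
            "flagged_pairs": [[a, b, float(r)] for a, b, r in self.flagged_pairs],
            "dropped": [[v, reason, None if d is None else float(d)]
                        for v, reason, d in self.dropped],
            "remaining": list(self.remaining),
            "stepwise_trace": self.stepwise_trace,
            "selected": list(self.selected),
            "notes": list(self.notes),
        }


def _subset_seed(base_seed: int, names) -> int:
    key = ",".join(sorted(names))
    h = hashlib.sha256(f"{base_seed}|{key}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _model_dic(df, names, y, model_spec: bayes.ModelSpec,
               W: WeightMatrix | None, cache: dict) -> float:
    key = frozenset(names)
    if key in cache:
        return cache[key]
    X = df[list(names)].to_numpy(dtype=float) if names else np.empty((len(y), 0))
    spec = bayes.ModelSpec(
        model=model_spec.model, covariate_names=tuple(names),
        prior_coef=model_spec.prior_coef, prior_u=model_spec.prior_u,
        prior_v=model_spec.prior_v, n_chains=model_spec.n_chains,
        n_iter=model_spec.n_iter, n_burnin=model_spec.n_burnin,
        thin=model_spec.thin, seed=_subset_seed(model_spec.seed, names))
    fit = bayes.fit(y, X, W, spec)
    cache[key] = fit.dic
    return fit.dic


def correlation_filter(data, candidates, y, threshold: float = 0.7,
                       model_spec: bayes.ModelSpec | None = None,
                       W: WeightMatrix | None = None,
                       report: ScreeningReport | None = None) -> ScreeningReport:
    """Drop the higher-DIC member of every |r| > threshold candidate pair.

    *data* is a DataFrame holding the candidate columns; *y* the outcome.
    Constant candidates are excluded upfront. The comparison uses strict
    ``>`` on |r|, so a pair at exactly the threshold is not flagged.
    """
    df = data.df if hasattr(data, "df") else data
    model_spec = model_spec or bayes.ModelSpec(model="iid", n_chains=1,
                                               n_iter=3000, n_burnin=1000)
    rep = report or ScreeningReport()
    y = np.asarray(y, dtype=float)
    if len(candidates) < 2:
        raise ValueError("need at least two candidates")

    alive = []
    for c in candidates:
        if df[c].std(ddof=0) == 0:
            rep.dropped.append((c, "zero variance", None))
        else:
            alive.append(c)
    corr = df[alive].corr(method="pearson")
    rep.correlation_matrix = corr

    pairs = []
    for i, a in enumerate(alive):
        for b in alive[i + 1:]:
            r = float(corr.loc[a, b])
            if abs(r) > threshold:
                pairs.append((a, b, r))
    pairs.sort(key=lambda t: (-abs(t[2]), t[0], t[1]))
    rep.flagged_pairs = pairs

    cache: dict = {}
    dropped_names = {v for v, _, _ in rep.dropped}
    for a, b, r in pairs:
        if a in dropped_names or b in dropped_names:
            continue
        dic_a = _model_dic(df, [a], y, model_spec, W, cache)
        dic_b = _model_dic(df, [b], y, model_spec, W, cache)
        if dic_a == dic_b:
            loser = max(a, b)
            rep.notes.append(f"DIC tie for ({a}, {b}); dropped {loser} "
                             "lexicographically")
        else:
            loser = a if dic_a > dic_b else b
        partner = b if loser == a else a
        rep.dropped.append((loser, f"|r|={abs(r):.3f} with {partner}",
                            cache[frozenset([loser])]))
        dropped_names.add(loser)
    rep.remaining = [c for c in alive if c not in dropped_names]
    return rep


def stepwise_select(data, candidates_or_report, y,
                    model_spec: bayes.ModelSpec | None = None,
                    W: WeightMatrix | None = None,
                    direction: str = "backward",
                    min_improvement: float = 0.0) -> ScreeningReport:
    """DIC-based stepwise selection over the remaining candidates.

    Backward: start from the full set; repeatedly remove the variable whose
    removal most decreases DIC; stop when no removal decreases DIC by more
    than ``min_improvement``. Forward: start empty and add symmetrically.
    The full trace (step, action, variable, DIC before/after) is recorded.
    """
    df = data.df if hasattr(data, "df") else data
    model_spec = model_spec or bayes.ModelSpec(model="iid", n_chains=1,
                                               n_iter=3000, n_burnin=1000)
    if isinstance(candidates_or_report, ScreeningReport):
        rep = candidates_or_report
        remaining = list(rep.remaining)
    else:
        remaining = list(candidates_or_report)
        rep = ScreeningReport(remaining=remaining)
    if not remaining:
        raise ValueError("no candidates remain for stepwise selection")
    if direction not in ("backward", "forward"):
        raise ValueError("direction must be 'backward' or 'forward'")

    cache: dict = {}
    y = np.asarray(y, dtype=float)
    step = 0
    if direction == "backward":
        current = sorted(remaining)
        dic_cur = _model_dic(df, current, y, model_spec, W, cache)
        while current:
            options = []
            for v in current:
                trial = [c for c in current if c != v]
                options.append((_model_dic(df, trial, y, model_spec, W, cache),
                                v))
            options.sort(key=lambda t: (t[0], t[1]))
            best_dic, best_var = options[0]
            if dic_cur - best_dic > min_improvement:
                step += 1
                rep.stepwise_trace.append({
                    "step": step, "action": "remove", "variable": best_var,
                    "dic_before": float(dic_cur), "dic_after": float(best_dic)})
                current = [c for c in current if c != best_var]
                dic_cur = best_dic
            else:
                break
    else:
        current = []
        dic_cur = _model_dic(df, current, y, model_spec, W, cache)
        pool = sorted(remaining)
        while pool:
            options = [(_model_dic(df, sorted(current + [v]), y, model_spec,
                                   W, cache), v) for v in pool]
            options.sort(key=lambda t: (t[0], t[1]))
            best_dic, best_var = options[0]
            if dic_cur - best_dic > min_improvement:
                step += 1
                rep.stepwise_trace.append({
                    "step": step, "action": "add", "variable": best_var,
                    "dic_before": float(dic_cur), "dic_after": float(best_dic)})
                current = sorted(current + [best_var])
                pool.remove(best_var)
                dic_cur = best_dic
            else:
                break
    rep.selected = [c for c in remaining if c in current] \
        if direction == "backward" else list(current)
    return rep
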