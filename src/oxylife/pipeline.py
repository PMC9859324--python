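"""End-to-end analysis pipeline.

Stages, in order: derive covariates -> descriptive 140 mmHg comparison ->
Pearson/DIC correlation filter -> stepwise DIC selection -> Moran's-I gate on
fixed-effects residuals -> fit the gated model (CAR or IID) -> optional YLL
clustering with between-cluster tests. Every random stage draws its seed
deterministically from the config seed, so a run is reproducible
byte-for-byte from its config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayes, cluster, hypoxia, screening, spatial
from .region_data import RegionTable, aggregate_stations, read_region_table

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

log = logging.getLogger("oxylife")

_DEFAULTS = {
    "region_csv": None,
    "station_csv": None,
    "yll_csv": None,
    "geojson": None,
    "out_dir": "oxylife_out",
    "seed": 0,
    "cutoff_mmhg": 140.0,
    "screening_threshold": 0.7,
    "screening_direction": "backward",
    "screening_family": "iid",
    "moran_permutations": 9999,
    "moran_alpha": 0.05,
    "moran_input": "residuals",       # or "raw"
    "cluster_k": 3,
    "standardize_yll": False,
    "covariates": None,               # default: all recognised columns
    "mcmc": {"n_chains": 4, "n_iter": 15000, "n_burnin": 5000, "thin": 1},
    "screening_mcmc": {"n_chains": 1, "n_iter": 3000, "n_burnin": 1000,
                       "thin": 1},
}


@dataclass
class PipelineConfig:
    region_csv: str
    station_csv: str | None = None
    yll_csv: str | None = None
    geojson: str | None = None
    out_dir: str = "oxylife_out"
    seed: int = 0
    cutoff_mmhg: float = 140.0
    screening_threshold: float = 0.7
    screening_direction: str = "backward"
    screening_family: str = "iid"
    moran_permutations: int = 9999
    moran_alpha: float = 0.05
    moran_input: str = "residuals"
    cluster_k: int = 3
    standardize_yll: bool = False
    covariates: list | None = None
    mcmc: dict = field(default_factory=lambda: dict(_DEFAULTS["mcmc"]))
    screening_mcmc: dict = field(
        default_factory=lambda: dict(_DEFAULTS["screening_mcmc"]))

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded)."""
        d = asdict(self)
        d.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def validate_config(source) -> PipelineConfig:
    """Build a PipelineConfig from a YAML path or a mapping.

    Unknown keys are rejected by name; out-of-range values raise with the
    offending key path.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    unknown = sorted(set(raw) - set(_DEFAULTS))
    if unknown:
        raise ValueError(f"unknown config key(s): {unknown}")
    if "region_csv" not in raw or raw["region_csv"] is None:
        raise ValueError("config must set 'region_csv'")
    merged = {**_DEFAULTS, **raw}
    for key in ("mcmc", "screening_mcmc"):
        block = {**_DEFAULTS[key], **(raw.get(key) or {})}
        bad = sorted(set(block) - {"n_chains", "n_iter", "n_burnin", "thin"})
        if bad:
            raise ValueError(f"unknown key(s) under '{key}': {bad}")
        merged[key] = block
    cfg = PipelineConfig(**merged)
    if not 0 < cfg.moran_alpha < 1:
        raise ValueError("moran_alpha must lie in (0, 1)")
    if cfg.screening_threshold <= 0:
        raise ValueError("screening_threshold must be positive")
    if cfg.moran_input not in ("residuals", "raw"):
        raise ValueError("moran_input must be 'residuals' or 'raw'")
    if cfg.screening_direction not in ("backward", "forward"):
        raise ValueError("screening_direction must be 'backward' or 'forward'")
    if cfg.screening_family not in ("iid", "car"):
        raise ValueError("screening_family must be 'iid' or 'car'")
    for path_key in ("region_csv", "station_csv", "yll_csv", "geojson"):
        p = getattr(cfg, path_key)
        if p is not None and not Path(p).exists():
            raise ValueError(f"{path_key}: path does not exist: {p}")
    return cfg


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (< 2^31)."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def run_pipeline(config: PipelineConfig | dict | str) -> dict:
    """Run the full analysis and return (and write) the report.

    The report is a JSON-serialisable dict with one section per stage;
    a stage that cannot run is recorded as skipped with its reason. All
    artifacts (tables, weights, draws summary, Newick tree, report JSON)
    are written under ``config.out_dir``.
    """
    cfg = config if isinstance(config, PipelineConfig) else validate_config(config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {"provenance": {"seed": cfg.seed, "config": asdict(cfg),
                             "config_hash": cfg.config_hash()}}
    t0 = time.time()

    regions = read_region_table(cfg.region_csv)
    if cfg.geojson:
        from .region_data import read_geometry

        cents = read_geometry(cfg.geojson).set_index("region_id")
        df = regions.df.set_index("region_id")
        df.loc[cents.index, ["lon", "lat"]] = cents[["lon", "lat"]]
        regions = RegionTable(df.reset_index())
    if cfg.station_csv:
        stations = pd.read_csv(cfg.station_csv, parse_dates=["date"])
        met = aggregate_stations(stations, region_ids=regions.region_ids)
        rename = {"sunshine": "sunshine_h", "wind": "wind_speed_mps",
                  "rel_humidity": "rel_humidity_pct",
                  "temperature": "temperature_C"}
        met = met.rename(columns=rename).drop(columns=["pressure"],
                                              errors="ignore")
        df = regions.df.set_index("region_id")
        for col in met.columns:
            df[col] = met[col]
        regions = RegionTable(df.reset_index())
    log.info("stage=load n_regions=%d elapsed=%.2fs", regions.n,
             time.time() - t0)

    candidates = list(cfg.covariates or regions.covariate_names)
    model_cols = ["oxygen"] + candidates
    analysed = regions.complete_cases(["life_expectancy", "oxygen",
                                       *candidates])
    report["n_regions"] = analysed.n
    report["n_excluded_missing"] = regions.n - analysed.n

    # --- descriptive stage -------------------------------------------------
    table1 = hypoxia.compare_groups(analysed, ["life_expectancy", "oxygen",
                                               *candidates],
                                    cutoff=cfg.cutoff_mmhg)
    table1.to_csv(out / "descriptive_comparison.csv", index=False)
    report["descriptive"] = table1.to_dict(orient="records")

    # --- screening ---------------------------------------------------------
    df = analysed.df.copy()
    # GDP per capita enters the model standardized
    if "gdp_per_capita" in df.columns:
        g = df["gdp_per_capita"]
        df["gdp_per_capita"] = (g - g.mean()) / g.std(ddof=1)
    y = df["life_expectancy"].to_numpy(dtype=float)

    W = spatial.inverse_distance_weights(analysed.centroids(),
                                         region_ids=analysed.region_ids)
    W.to_dense_csv(out / "weights.csv")

    screen_spec = bayes.ModelSpec(model=cfg.screening_family,
                                  seed=_stage_seed(cfg.seed, "screening"),
                                  **cfg.screening_mcmc)
    screen_W = W if cfg.screening_family == "car" else None
    rep = screening.correlation_filter(
        df, candidates, y=y, threshold=cfg.screening_threshold,
        model_spec=screen_spec, W=screen_W)
    rep = screening.stepwise_select(df, rep, y=y, model_spec=screen_spec,
                                    W=screen_W,
                                    direction=cfg.screening_direction)
    report["screening"] = rep.to_dict()
    with open(out / "screening.json", "w") as fh:
        json.dump(rep.to_dict(), fh, indent=2, sort_keys=True)
    selected = ["oxygen"] + list(rep.selected)
    log.info("stage=screening selected=%s", selected)

    # --- Moran gate ---------------------------------------------------------
    X_sel = df[selected].to_numpy(dtype=float)
    if cfg.moran_input == "raw":
        moran = spatial.morans_i(y, W,
                                 n_permutations=cfg.moran_permutations,
                                 seed=_stage_seed(cfg.seed, "moran"))
    else:
        moran = spatial.morans_i_residuals(
            y, X_sel, W, n_permutations=cfg.moran_permutations,
            seed=_stage_seed(cfg.seed, "moran"))
    moran.to_json(out / "moran.json")
    chosen = bayes.select_spatial_model(moran, alpha=cfg.moran_alpha)
    report["moran"] = json.loads(moran.to_json())
    report["chosen_model"] = chosen
    log.info("stage=moran I=%.3f p=%.4f model=%s", moran.I, moran.p_value,
             chosen)

    # --- model fit ----------------------------------------------------------
    spec = bayes.ModelSpec(model=chosen, covariate_names=tuple(selected),
                           seed=_stage_seed(cfg.seed, "fit"), **cfg.mcmc)
    fit_res = bayes.fit(y, X_sel, W if chosen == "car" else None, spec)
    report["fit"] = fit_res.summaries_json()
    fit_res.summaries.to_csv(out / "fit_summaries.csv")
    fit_res.draws_frame().to_csv(out / "fit_draws.csv", index=False)
    with open(out / "fit.json", "w") as fh:
        json.dump(fit_res.summaries_json(), fh, indent=2, sort_keys=True)
    log.info("stage=fit model=%s dic=%.1f adjR2=%.3f", chosen, fit_res.dic,
             fit_res.adjusted_r2_full)

    # --- YLL clustering -----------------------------------------------------
    if cfg.yll_csv:
        Y = cluster.YLLMatrix.from_csv(cfg.yll_csv)
        res = cluster.ward_cluster(Y, k=cfg.cluster_k,
                                   standardize=cfg.standardize_yll)
        oxy = analysed.df.set_index("region_id")["oxygen"]
        oxy = oxy.reindex(res.labels.index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tests = cluster.compare_clusters(Y, res.labels, oxygen=oxy)
        nwk, link_df = cluster.export_dendrogram(res)
        (out / "dendrogram.nwk").write_text(nwk + "\n")
        link_df.to_csv(out / "linkage.csv", index=False)
        tbl = cluster.cluster_tests_table(tests)
        tbl.to_csv(out / "cluster_tests.csv", index=False)
        report["cluster"] = {
            "k": cfg.cluster_k,
            "labels": {str(k): int(v) for k, v in res.labels.items()},
            "tests": json.loads(tbl.to_json(orient="records")),
        }
        log.info("stage=cluster k=%d", cfg.cluster_k)
    else:
        report["cluster"] = {"skipped": "no YLL matrix supplied"}

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
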