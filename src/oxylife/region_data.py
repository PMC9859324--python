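"""Regional input tables and derived covariates.

The analysis operates on one row per spatial unit (province or municipality):
life expectancy as the outcome, ambient oxygen concentration as the exposure,
and a set of socioeconomic and meteorological covariates. Oxygen is not
measured directly but derived from barometric pressure; health-resource and
education covariates are derived from administrative counts. Daily station
observations, when supplied, are averaged within their assigned regions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import shape

__all__ = [
    "COVARIATE_NAMES",
    "RegionTable",
    "ValidationError",
    "oxygen_from_pressure",
    "avg_years_education",
    "health_tech_per_1000",
    "aggregate_stations",
    "read_region_table",
    "read_geometry",
    "assign_stations_to_regions",
]

#: Atmospheric molar fraction of oxygen.
OXYGEN_FRACTION = 0.2093
#: Unit conversion, mmHg per kPa.
MMHG_PER_KPA = 7.5

#: Canonical covariate columns recognised by the pipeline, in display order.
COVARIATE_NAMES = (
    "gdp_per_capita",        # 10^4 currency units
    "health_tech_per_1000",  # health technicians per 1000 residents
    "edu_years",             # average years of education
    "sunshine_h",            # daily sunshine hours (annual mean)
    "temperature_C",         # annual mean temperature
    "rel_humidity_pct",      # annual mean relative humidity
    "wind_speed_mps",        # annual mean wind speed
)

#: Meteorological variables carried by station records.
STATION_VARIABLES = ("pressure", "sunshine", "wind", "rel_humidity", "temperature")

REQUIRED_REGION_COLUMNS = ("region_id", "lon", "lat", "life_expectancy")


class ValidationError(ValueError):
    """An input table violated a structural or range constraint."""


def oxygen_from_pressure(pressure):
    """Ambient oxygen partial pressure (mmHg) from barometric pressure (kPa).

    Oxygen makes up 20.93% of the atmosphere by volume, so its partial
    pressure is ``pressure * 0.2093``, converted to mmHg at 7.5 mmHg/kPa.
    Accepts scalars or arrays; negative pressures are rejected.
    """
    p = np.asarray(pressure, dtype=float)
    if np.any(p < 0):
        raise ValidationError("barometric pressure must be non-negative")
    out = p * OXYGEN_FRACTION * MMHG_PER_KPA
    return float(out) if np.isscalar(pressure) or out.ndim == 0 else out


def health_tech_per_1000(personnel, residents):
    """Health technicians per 1000 permanent residents."""
    personnel = np.asarray(personnel, dtype=float)
    residents = np.asarray(residents, dtype=float)
    if np.any(residents <= 0):
        raise ValidationError("number of residents must be positive")
    if np.any(personnel < 0):
        raise ValidationError("personnel count must be non-negative")
    out = personnel / residents * 1000.0
    return float(out) if out.ndim == 0 else out


def avg_years_education(n_university, n_highschool, n_middleschool, n_primary,
                        n_noschool):
    """Population-average years of education from attainment counts.

    Completed-stage weights: university 16 y, high school 12 y, middle
    school 9 y, primary 6 y, no schooling 0 y; divisor is the total of the
    five counts (population aged six and over). The stage weights assume
    completion, which slightly overstates attainment where dropout occurs;
    no correction is applied.
    """
    counts = np.asarray(
        [n_university, n_highschool, n_middleschool, n_primary, n_noschool],
        dtype=float,
    )
    if np.any(counts < 0):
        raise ValidationError("attainment counts must be non-negative")
    total = counts.sum(axis=0)
    if np.any(total <= 0):
        raise ValidationError("total population must be positive")
    weights = np.array([16.0, 12.0, 9.0, 6.0, 0.0])
    out = (weights @ counts) / total
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class RegionTable:
    """Validated per-region analysis table.

    Wraps a DataFrame with one row per spatial unit, guaranteeing unique
    region identifiers, in-range coordinates and outcomes, and a resolved
    ``oxygen`` column (derived from ``pressure`` when absent).
    """

    df: pd.DataFrame
    covariate_names: tuple = field(default=())

    def __post_init__(self):
        df = self.df
        missing = [c for c in REQUIRED_REGION_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing required column(s): {missing}")
        if df["region_id"].duplicated().any():
            dups = df.loc[df["region_id"].duplicated(), "region_id"].tolist()
            raise ValidationError(f"duplicate region_id(s): {dups}")
        for col in ("lon", "lat", "life_expectancy", "oxygen", "pressure"):
            if col in df.columns and not pd.api.types.is_numeric_dtype(df[col]):
                raise ValidationError(f"column {col!r} must be numeric")
        if "oxygen" not in df.columns:
            if "pressure" not in df.columns:
                raise ValidationError(
                    "need an 'oxygen' column (mmHg) or a 'pressure' column (kPa)")
            df = df.copy()
            df["oxygen"] = oxygen_from_pressure(df["pressure"].to_numpy())
            self.df = df
        if not df["lat"].between(-90, 90).all():
            raise ValidationError("lat out of [-90, 90]")
        if not df["lon"].between(-180, 180).all():
            raise ValidationError("lon out of [-180, 180]")
        le = df["life_expectancy"]
        if not ((le > 0) & (le < 120) | le.isna()).all():
            raise ValidationError("life_expectancy out of (0, 120)")
        ox = df["oxygen"].dropna()
        if not (ox > 0).all():
            raise ValidationError("oxygen must be positive where present")
        if not self.covariate_names:
            self.covariate_names = tuple(
                c for c in COVARIATE_NAMES if c in df.columns)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def region_ids(self):
        return self.df["region_id"].to_numpy()

    def centroids(self) -> np.ndarray:
        """(n, 2) array of (lon, lat)."""
        return self.df[["lon", "lat"]].to_numpy(dtype=float)

    def complete_cases(self, columns) -> "RegionTable":
        """Subset to rows with no missing values in *columns*, logging drops."""
        cols = list(columns)
        mask = self.df[cols].notna().all(axis=1)
        n_drop = int((~mask).sum())
        if n_drop:
            warnings.warn(
                f"excluding {n_drop} region(s) with missing values in {cols}",
                stacklevel=2)
        return RegionTable(self.df.loc[mask].reset_index(drop=True),
                           self.covariate_names)


def read_region_table(path) -> RegionTable:
    """Read and validate a region CSV (UTF-8, header row)."""
    df = pd.read_csv(path)
    return RegionTable(df)


def read_geometry(path) -> pd.DataFrame:
    """Read a GeoJSON FeatureCollection and return per-feature centroids.

    Features must carry a ``region_id`` property. Returns a DataFrame with
    columns region_id, lon, lat; polygon centroids are area-weighted.
    """
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    feats = gj.get("features", [])
    rows = []
    for feat in feats:
        props = feat.get("properties") or {}
        if "region_id" not in props:
            raise ValidationError("GeoJSON feature lacks a 'region_id' property")
        geom = shape(feat["geometry"])
        c = geom.centroid
        rows.append({"region_id": props["region_id"], "lon": c.x, "lat": c.y})
    return pd.DataFrame(rows, columns=["region_id", "lon", "lat"])


def aggregate_stations(records: pd.DataFrame, region_ids=None) -> pd.DataFrame:
    """Per-region annual means of station meteorology.

    *records* has one row per station-day with columns ``station_id``,
    ``region_id``, ``inhabited`` plus the meteorological variables
    (any subset of pressure, sunshine, wind, rel_humidity, temperature).
    Stations flagged uninhabited are excluded before averaging; each
    region's value is the plain arithmetic mean over all retained daily
    records. Regions listed in *region_ids* but observed by no retained
    station get NaN rows rather than fabricated values.
    """
    variables = [v for v in STATION_VARIABLES if v in records.columns]
    if records.empty:
        warnings.warn("no station records supplied", stacklevel=2)
        out = pd.DataFrame(columns=variables)
        out.index.name = "region_id"
    else:
        if "region_id" not in records.columns:
            raise ValidationError("station records need a 'region_id' column")
        kept = records
        if "inhabited" in records.columns:
            kept = records[records["inhabited"].astype(bool)]
        if "pressure" in kept.columns and (kept["pressure"] <= 0).any():
            raise ValidationError("station pressure must be positive")
        if "rel_humidity" in kept.columns and not kept["rel_humidity"].between(0, 100).all():
            raise ValidationError("relative humidity out of [0, 100]")
        out = kept.groupby("region_id")[variables].mean()
    if region_ids is not None:
        out = out.reindex(pd.Index(region_ids, name="region_id"))
    return out


def assign_stations_to_regions(stations: pd.DataFrame, geojson_path) -> pd.DataFrame:
    """Optional helper: assign stations to regions by point-in-polygon.

    *stations* needs lon/lat columns; returns a copy with a ``region_id``
    column (NaN where no polygon contains the point).
    """
    from shapely.geometry import Point

    with open(geojson_path, encoding="utf-8") as fh:
        gj = json.load(fh)
    polys = [(f["properties"]["region_id"], shape(f["geometry"]))
             for f in gj.get("features", [])]
    out = stations.copy()
    assigned = []
    for lon, lat in zip(out["lon"], out["lat"]):
        pt = Point(lon, lat)
        rid = next((r for r, g in polys if g.contains(pt) or g.touches(pt)), None)
        assigned.append(rid)
    out["region_id"] = assigned
    return out
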