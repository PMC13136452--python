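"""File formats and pipeline configuration.

GeoJSON is the canonical geometry interchange (single text file,
diff-able); tabular inputs and outputs are plain CSV.  Geometry tables are
pandas DataFrames with shapely geometries, written/read losslessly through
``shapely.geometry.mapping``/``shape``.  Numeric CSV serialization keeps
full double precision (display rounding happens only in human-readable
report views).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .exposure import PollutionGrid

VALID_GRADES = {"A", "B", "C", "D"}


class SchemaError(ValueError):
    """An input file does not carry the declared fields/values."""


def write_geojson(df: pd.DataFrame, path: str | Path,
                  properties: list[str] | None = None) -> None:
    """Write a geometry DataFrame as a GeoJSON FeatureCollection."""
    props = properties if properties is not None else [c for c in df.columns
                                                       if c != "geometry"]
    features = [{"type": "Feature",
                 "geometry": mapping(row.geometry),
                 "properties": {p: getattr(row, p) for p in props}}
                for row in df.itertuples(index=False)]
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, sort_keys=True))


def read_geojson(path: str | Path) -> pd.DataFrame:
    """Read a GeoJSON FeatureCollection into a geometry DataFrame."""
    path = Path(path)
    if path.suffix.lower() in {".shp", ".shx", ".dbf"}:
        raise SchemaError(
            "shapefile reading is not supported; convert the layer to GeoJSON "
            "(e.g. `ogr2ogr -f GeoJSON out.geojson in.shp`)")
    data = json.loads(path.read_text())
    if data.get("type") != "FeatureCollection":
        raise SchemaError(f"{path} is not a GeoJSON FeatureCollection")
    rows = []
    for feat in data["features"]:
        rows.append({**feat.get("properties", {}),
                     "geometry": shape(feat["geometry"])})
    return pd.DataFrame(rows)


def _require_fields(df: pd.DataFrame, fields: list[str], path) -> None:
    missing = [f for f in fields if f not in df.columns]
    if missing:
        candidates = [c for c in df.columns if c != "geometry"]
        raise SchemaError(f"{path}: missing field(s) {missing}; "
                          f"available: {candidates}")


def _repair(df: pd.DataFrame, repair_invalid: bool, what: str) -> pd.DataFrame:
    from .redlining_score import GeometryError
    bad = [i for i, g in enumerate(df.geometry) if not g.is_valid]
    if not bad:
        return df
    if not repair_invalid:
        raise GeometryError(f"{what}: invalid geometry at rows {bad[:5]}")
    df = df.copy()
    for i in bad:
        df.iat[i, df.columns.get_loc("geometry")] = df.geometry.iloc[i].buffer(0)
    return df


def read_tracts(path: str | Path, id_field: str = "GEOID",
                area_field: str = "ALAND", repair_invalid: bool = True,
                ) -> pd.DataFrame:
    """Read a tract layer; land_area falls back to polygon area when the
    area field is absent (census ALAND excludes water; synthetic layers
    have none)."""
    df = read_geojson(path)
    _require_fields(df, [id_field], path)
    df = _repair(df, repair_invalid, f"tracts {path}")
    out = pd.DataFrame({"tract_id": df[id_field].astype(str),
                        "geometry": df.geometry})
    out["land_area"] = (pd.to_numeric(df[area_field]) if area_field in df.columns
                        else [g.area for g in df.geometry])
    return out


def read_holc(path: str | Path, grade_field: str = "holc_grade",
              id_field: str | None = None, on_bad_grade: str = "error",
              repair_invalid: bool = True) -> pd.DataFrame:
    """Read an HOLC grade layer, validating grades against A–D.

    ``on_bad_grade``: "error" rejects the file with a row-level message,
    "skip" drops offending rows.
    """
    df = read_geojson(path)
    _require_fields(df, [grade_field], path)
    df = _repair(df, repair_invalid, f"HOLC areas {path}")
    grades = df[grade_field].astype(str)
    bad = ~grades.isin(VALID_GRADES)
    if bad.any():
        msg = (f"{path}: invalid HOLC grade(s) "
               f"{sorted(grades[bad].unique())} at rows {list(df.index[bad])[:5]}")
        if on_bad_grade == "error":
            raise SchemaError(msg)
        df, grades = df.loc[~bad], grades.loc[~bad]
    ids = (df[id_field].astype(str) if id_field and id_field in df.columns
           else [f"{g}-{i}" for i, g in enumerate(grades)])
    return pd.DataFrame({"area_id": ids, "geometry": df.geometry.to_numpy(),
                         "grade": grades.to_numpy()})


def write_grid_csv(grid: PollutionGrid, values_path: str | Path,
                   cells_path: str | Path) -> None:
    """Grid values as ``cell_id,date,value`` CSV plus a cell GeoJSON."""
    out = grid.values.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(values_path, index=False)
    write_geojson(grid.cells, cells_path)


def read_grid_csv(values_path: str | Path, cells_path: str | Path,
                  pollutant: str) -> PollutionGrid:
    values = pd.read_csv(values_path, parse_dates=["date"])
    cells = read_geojson(cells_path)
    if "cell_id" not in cells.columns:
        raise SchemaError(f"{cells_path}: cell layer needs a cell_id property")
    return PollutionGrid(pollutant=pollutant, cells=cells, values=values)


def write_scores_csv(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, index=False)


def read_scores_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_fields(df, ["tract_id", "category"], path)
    return df.astype({"tract_id": str})


def read_panel_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_fields(df, ["tract_id", "year", "mean"], path)
    return df.astype({"tract_id": str})


_CONFIG_FIELDS: dict[str, object] = {}


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings with documented defaults."""

    # synthetic city (used when no input paths are given)
    nx: int = 10
    ny: int = 10
    cell_m: float = 1000.0
    grid_cell_m: float | None = None
    years: tuple[int, int] = (2000, 2016)
    pollutant: str = "no2"
    seed: int = 0
    # ingestion
    tracts_path: str | None = None
    holc_path: str | None = None
    grid_values_path: str | None = None
    grid_cells_path: str | None = None
    census_path: str | None = None
    svi_path: str | None = None
    id_field: str = "GEOID"
    area_field: str = "ALAND"
    grade_field: str = "holc_grade"
    # scoring
    sliver_m2: float = 1.0
    # aggregation
    min_coverage: float = 0.8
    min_day_frac: float = 0.75
    screen: str | None = None          # None | "robust_z" | "manual_list"
    screen_threshold: float = 5.0
    screen_min_run_days: int = 14
    manual_exclusions: list = field(default_factory=list)
    # trend model
    reference: str = "A"
    year_origin: int | None = None
    report_years: tuple[int, ...] = (2000, 2008, 2016)
    alpha: float = 0.05
    gate_contrasts: bool = True

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def validate(self) -> None:
        if not 0 < self.min_day_frac <= 1:
            raise SchemaError("min_day_frac must lie in (0, 1]")
        if not 0 <= self.min_coverage <= 1:
            raise SchemaError("min_coverage must lie in [0, 1]")
        if self.sliver_m2 < 0 or self.screen_threshold <= 0:
            raise SchemaError("sliver_m2 must be >= 0 and screen_threshold > 0")
        if not 0 < self.alpha < 1:
            raise SchemaError("alpha must lie in (0, 1)")
        if self.screen not in (None, "robust_z", "manual_list"):
            raise SchemaError(f"unknown screening method {self.screen!r}")

    def to_log_dict(self) -> dict:
        return dataclasses.asdict(self)
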