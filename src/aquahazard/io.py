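"""Readers and writers for the pipeline's file formats.

Everything is plain text: well tables and result tables as CSV, district
polygons as GeoJSON FeatureCollections (properties ``id``,
``population``, ``climate_zone``), rasters as ESRI ASCII grids (.asc).
Coordinates in the synthetic world are planar kilometres; an optional
CRS string on the district file is carried through opaquely for
real-data users (no reprojection happens inside the tool).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .grids import GridSpec, ParameterGrid
from .regions import ClimateZone, District, DistrictMap
from .standards import INDEX_PARAMETERS

__all__ = [
    "read_wells",
    "write_wells",
    "read_districts",
    "write_districts",
    "read_grid_ascii",
    "write_grid_ascii",
    "read_station_series",
]

MANDATORY_WELL_COLUMNS = ("well_id", "x", "y")


def read_wells(path: str | Path) -> pd.DataFrame:
    """Read and validate a well-record CSV.

    Requires ``well_id, x, y`` columns; ``district_id``, ``climate_zone``
    and ``depth`` are optional; any recognized parameter column is kept
    as float with empty cells as missing (never zero).  Duplicate well
    ids and negative concentrations are rejected with row numbers.
    """
    table = pd.read_csv(path)
    missing = [c for c in MANDATORY_WELL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    dup = table["well_id"][table["well_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate well_id values: {sorted(set(dup))}")
    for p in INDEX_PARAMETERS:
        if p not in table.columns:
            continue
        col = pd.to_numeric(table[p], errors="coerce")
        bad = table.index[(col < 0).fillna(False)]
        if len(bad):
            rows = [int(i) + 2 for i in bad]  # 1-based incl. header
            raise ValueError(f"{path}: negative {p} concentrations at rows {rows}")
        table[p] = col
    return table


def write_wells(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.10g")


def write_districts(districts: DistrictMap, path: str | Path) -> None:
    features = []
    for d in sorted(districts.districts, key=lambda d: d.id):
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(d.polygon),
                "properties": {
                    "id": d.id,
                    "population": int(d.population),
                    "climate_zone": d.climate_zone.value,
                },
            }
        )
    doc = {
        "type": "FeatureCollection",
        "bbox": list(districts.bounds),
        "features": features,
    }
    if districts.crs:
        doc["crs_name"] = districts.crs
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(doc))


def read_districts(path: str | Path) -> DistrictMap:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    districts = []
    for feat in doc["features"]:
        props = feat.get("properties", {})
        for key in ("id", "population", "climate_zone"):
            if key not in props:
                raise ValueError(f"{path}: feature missing property {key!r}")
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            raise ValueError(f"{path}: invalid geometry for district {props['id']}")
        districts.append(
            District(
                id=str(props["id"]),
                polygon=geom,
                climate_zone=ClimateZone(props["climate_zone"]),
                population=int(props["population"]),
            )
        )
    if "bbox" in doc:
        bounds = tuple(doc["bbox"])
    else:
        xs0, ys0, xs1, ys1 = zip(*(d.polygon.bounds for d in districts))
        bounds = (min(xs0), min(ys0), max(xs1), max(ys1))
    return DistrictMap(districts=districts, bounds=bounds, crs=doc.get("crs_name"))


def write_grid_ascii(grid: ParameterGrid, path: str | Path) -> None:
    """ESRI ASCII grid (row 1 = northernmost row, per the format)."""
    spec = grid.spec
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {float(spec.x_min):.12g}\n"
        f"yllcorner {float(spec.y_min):.12g}\n"
        f"cellsize {float(spec.cell_size):.12g}\n"
        f"NODATA_value -9999\n"
    )
    body = grid.values[::-1]  # internal row 0 is southernmost
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, np.where(np.isnan(body), -9999.0, body), fmt="%.10g")


def read_grid_ascii(path: str | Path, parameter: str = "") -> ParameterGrid:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)[::-1]
    values = np.where(values == hdr.get("nodata_value", -9999.0), np.nan, values)
    spec = GridSpec(
        x_min=hdr["xllcorner"],
        y_min=hdr["yllcorner"],
        x_max=hdr["xllcorner"] + hdr["ncols"] * hdr["cellsize"],
        y_max=hdr["yllcorner"] + hdr["nrows"] * hdr["cellsize"],
        cell_size=hdr["cellsize"],
    )
    return ParameterGrid(parameter=parameter, spec=spec, values=values)


def read_station_series(path: str | Path) -> pd.DataFrame:
    """Tidy station CSV: columns station, date (ISO 8601), parameter,
    value and optionally unit."""
    table = pd.read_csv(path)
    needed = [c for c in ("station", "date", "parameter", "value") if c not in table.columns]
    if needed:
        raise ValueError(f"{path}: missing columns {needed}")
    table["date"] = pd.to_datetime(table["date"])
    table["value"] = pd.to_numeric(table["value"])
    return table
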