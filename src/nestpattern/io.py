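"""Typed readers and writers for the pipeline's plain-text formats.

Nests: CSV with columns id, year, x, y, laying_date (ISO 8601 or empty).
Leks: CSV with id, x, y, active_years (semicolon-separated year list).
Landscape features: one GeoJSON FeatureCollection with features named
"region" (Polygon/MultiPolygon), "shore" and "edge" (LineString).
Rasters: ESRI ASCII grid (see :class:`~nestpattern.suitability.RasterGrid`).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .geometry import PointSet, SpatialFeatureSet

log = logging.getLogger("nestpattern")

__all__ = [
    "read_nests_csv",
    "write_nests_csv",
    "read_leks_csv",
    "read_features_geojson",
    "write_features_geojson",
    "write_region_geojson",
    "read_feature_set",
]


def read_nests_csv(path, region=None, require_laying_date: bool = False):
    """Read the nest table, applying the exclusion rules.

    Rows lacking id/year/x/y (or, with ``require_laying_date``, a laying
    date) or falling outside ``region`` are dropped; the exclusion counts
    are logged and returned.

    Returns
    -------
    (nests_by_year, table, exclusions)
        ``{year: PointSet}``, the retained DataFrame, and a dict of counts.
    """
    table = pd.read_csv(path)
    required = ["id", "year", "x", "y"]
    missing_cols = [c for c in required if c not in table.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required column(s) {missing_cols}")
    n_in = len(table)
    keep = table[required].notna().all(axis=1)
    if require_laying_date:
        if "laying_date" not in table.columns:
            raise ValueError(f"{path}: laying_date column required but absent")
        ld = table["laying_date"].astype("string").str.strip()
        keep &= ld.notna() & (ld != "")
    n_missing = int((~keep).sum())
    table = table[keep]
    n_outside = 0
    if region is not None:
        from .geometry import contains_xy

        inside = contains_xy(region, table["x"].to_numpy(float), table["y"].to_numpy(float))
        n_outside = int((~inside).sum())
        table = table[inside]
    exclusions = {"read": n_in, "excluded_missing": n_missing,
                  "excluded_outside": n_outside, "retained": len(table)}
    log.info("nests: %(read)d read, %(excluded_missing)d missing-field, "
             "%(excluded_outside)d outside region, %(retained)d retained", exclusions)
    table = table.reset_index(drop=True)
    nests_by_year = {
        year: PointSet(grp[["x", "y"]].to_numpy(float), label=str(year))
        for year, grp in table.groupby("year")
    }
    return nests_by_year, table, exclusions


def write_nests_csv(nests_by_year: dict, path) -> None:
    rows = []
    i = 0
    for year, pts in nests_by_year.items():
        for x, y in pts.coords:
            rows.append({"id": f"nest{i:04d}", "year": year, "x": x, "y": y, "laying_date": ""})
            i += 1
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def read_leks_csv(path):
    """Lek centres and their active-year sets.

    Returns ``(coords, active_years, ids)``; years are parsed as int when
    possible, else kept as strings.
    """
    table = pd.read_csv(path)
    for c in ("id", "x", "y", "active_years"):
        if c not in table.columns:
            raise ValueError(f"{path}: missing required column {c!r}")

    def parse_years(cell):
        out = set()
        for tok in str(cell).split(";"):
            tok = tok.strip()
            if not tok:
                continue
            try:
                out.add(int(tok))
            except ValueError:
                out.add(tok)
        return out

    coords = table[["x", "y"]].to_numpy(float)
    active = [parse_years(c) for c in table["active_years"]]
    return coords, active, list(table["id"].astype(str))


def read_features_geojson(path):
    """Region, shore and edge geometries from one FeatureCollection."""
    with open(path) as fh:
        gj = json.load(fh)
    geoms = {}
    for feat in gj.get("features", []):
        name = (feat.get("properties") or {}).get("name")
        if name:
            geoms[name] = shape(feat["geometry"])
    for required in ("region", "shore", "edge"):
        if required not in geoms:
            raise ValueError(f"{path}: no feature named {required!r}")
    return geoms


def write_features_geojson(features: SpatialFeatureSet, path) -> None:
    def feat(name, geom):
        return {"type": "Feature", "properties": {"name": name}, "geometry": mapping(geom)}

    gj = {
        "type": "FeatureCollection",
        "features": [
            feat("region", features.region),
            feat("shore", features.shore),
            feat("edge", features.edge),
        ],
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)


def write_region_geojson(region, path, properties=None) -> None:
    gj = {"type": "FeatureCollection",
          "features": [{"type": "Feature", "properties": properties or {"name": "region"},
                        "geometry": mapping(region)}]}
    with open(path, "w") as fh:
        json.dump(gj, fh)


def read_feature_set(features_path, leks_path) -> SpatialFeatureSet:
    """Assemble a :class:`SpatialFeatureSet` from GeoJSON + lek CSV."""
    geoms = read_features_geojson(features_path)
    coords, active, ids = read_leks_csv(leks_path)
    return SpatialFeatureSet(region=geoms["region"], shore=geoms["shore"],
                             edge=geoms["edge"], lek_coords=coords,
                             lek_active_years=active, lek_ids=ids)
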