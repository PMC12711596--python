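"""Plain-text vector I/O: zone polygons and wind-farm points as GeoJSON.

Occurrence tables and presence/absence sets travel as CSV through pandas;
rasters through :mod:`esdm.grid`'s ASCII-grid functions. This module covers
the remaining formats with json + shapely only.
"""

from __future__ import annotations

import json

import pandas as pd
from shapely.geometry import mapping, shape

from .synthetic import ZoneSet

__all__ = [
    "write_zones_geojson",
    "read_zones_geojson",
    "write_windfarms_geojson",
    "read_windfarms_geojson",
]


def write_zones_geojson(zones: ZoneSet, path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"label": label},
            "geometry": mapping(poly),
        }
        for label, poly in zip(zones.labels, zones.polygons)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_zones_geojson(path) -> ZoneSet:
    with open(path) as fh:
        fc = json.load(fh)
    labels = [f["properties"]["label"] for f in fc["features"]]
    polys = [shape(f["geometry"]) for f in fc["features"]]
    return ZoneSet(labels, polys)


def write_windfarms_geojson(farms: pd.DataFrame, path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {
                "name": row["name"],
                "capacity_mw": float(row["capacity_mw"]),
                "status": row["status"],
            },
            "geometry": {"type": "Point",
                         "coordinates": [float(row["x"]), float(row["y"])]},
        }
        for _, row in farms.iterrows()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_windfarms_geojson(path) -> pd.DataFrame:
    with open(path) as fh:
        fc = json.load(fh)
    rows = []
    for f in fc["features"]:
        x, y = f["geometry"]["coordinates"]
        rows.append({**f["properties"], "x": x, "y": y})
    return pd.DataFrame(rows)
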