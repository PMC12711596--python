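"""Zonal suitable-area accounting and wind-farm footprint overlap.

Zonal statistics assign each raster cell to the polygon containing its centre
(the raster convention), so per-zone suitable areas over a partition sum
exactly to the whole-map figure. Wind-farm overlap converts installed
capacity to a cleared-land footprint at 0.3 ha/MW, draws a circular buffer of
that area around each farm point, counts the suitable cells whose centres fall
inside, and converts counts to km2 with a configurable per-pixel area
(default 0.8606 km2, the area of a 30 arc-second pixel at the reference
equatorial radius; synthetic landscapes use cell_size squared instead).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point

from .grid import RasterGrid
from .synthetic import STATUSES, ZoneSet

__all__ = [
    "CLEARED_HA_PER_MW",
    "pixel_area_km2_from_arcsec",
    "zonal_suitable",
    "cleared_area_ha",
    "farm_buffer",
    "windfarm_overlap",
]

#: Land clearing per installed megawatt of wind capacity (hectares).
CLEARED_HA_PER_MW = 0.3

#: Reference equatorial radius used for the arc-second pixel-area constant (km).
EQUATORIAL_RADIUS_KM = 6378.137


def pixel_area_km2_from_arcsec(arcsec: float = 30.0,
                               radius_km: float = EQUATORIAL_RADIUS_KM) -> float:
    """Area of a square pixel of ``arcsec`` arc-seconds at the reference radius."""
    side = radius_km * math.radians(arcsec / 3600.0)
    return side * side


def zonal_suitable(binary: RasterGrid, zones: ZoneSet,
                   pixel_area_km2: float) -> pd.DataFrame:
    """Per-zone suitable area from a binary map.

    A cell belongs to the zone containing (covering) its centre; the first
    matching zone wins, so a partition assigns each cell exactly once. Zones
    with zero cells are reported with NaN percent rather than dropped.
    """
    X, Y = binary.centre_grids()
    xs, ys = X.ravel(), Y.ravel()
    vals = binary.values.ravel()
    valid = np.isfinite(vals)
    assigned = np.full(xs.shape, -1, dtype=int)
    for k, poly in enumerate(zones.polygons):
        free = valid & (assigned < 0)
        if not free.any():
            break
        hits = shapely.contains_xy(poly, xs[free], ys[free])
        # boundary centres: contains misses them, covers picks them up
        if not hits.all():
            misses = np.nonzero(~hits)[0]
            pts = shapely.points(xs[free][misses], ys[free][misses])
            hits[misses] = shapely.covers(poly, pts)
        idx = np.nonzero(free)[0][hits]
        assigned[idx] = k
    rows = []
    for k, label in enumerate(zones.labels):
        in_zone = assigned == k
        n_cells = int(in_zone.sum())
        n_suit = int((vals[in_zone] == 1).sum())
        rows.append({
            "zone": label,
            "zone_cells": n_cells,
            "suitable_cells": n_suit,
            "zone_km2": n_cells * pixel_area_km2,
            "suitable_km2": n_suit * pixel_area_km2,
            "percent_suitable": 100.0 * n_suit / n_cells if n_cells else float("nan"),
        })
    return pd.DataFrame(rows)


def cleared_area_ha(capacity_mw: float) -> float:
    """Cleared land (hectares) for an installed capacity, at 0.3 ha/MW."""
    if not capacity_mw > 0:
        raise ValueError("capacity must be positive")
    return CLEARED_HA_PER_MW * capacity_mw


def _buffer_radius_km(capacity_mw: float) -> float:
    area_km2 = cleared_area_ha(capacity_mw) / 100.0
    return math.sqrt(area_km2 / math.pi)


def farm_buffer(x: float, y: float, capacity_mw: float):
    """Circular cleared-footprint buffer (64-segment polygon) around a farm."""
    return Point(x, y).buffer(_buffer_radius_km(capacity_mw), quad_segs=16)


def windfarm_overlap(binary: RasterGrid, farms: pd.DataFrame,
                     pixel_area_km2: float = 0.8606) -> dict[str, pd.DataFrame]:
    """Suitable-habitat overlap of wind-farm cleared footprints.

    Per farm, suitable cells are those whose centres lie within the circular
    buffer (a centre-in-disc test — identical to the buffer polygon up to its
    64-segment discretisation). Returns ``{"farms": per-farm table,
    "status": per-status table}``; the status table aggregates cleared km2,
    suitable km2 and percent overlap, plus a merged-union percent that counts
    each cell once even where buffers of the same status overlap.

    Farms outside the raster extent are excluded with a warning and reported
    via the ``in_extent`` column. Buffers smaller than a pixel can quantise to
    zero cells (or to one whole cell), so per-status percent is a pixel-count
    statistic, not an exact geometric one.
    """
    bad_status = set(farms["status"]) - set(STATUSES)
    if bad_status:
        raise ValueError(f"unknown wind-farm status values: {sorted(bad_status)}")
    if (farms["capacity_mw"] <= 0).any():
        raise ValueError("capacities must be positive")
    X, Y = binary.centre_grids()
    suit = binary.values == 1
    xs, ys = X[suit], Y[suit]

    x0, y0, x1, y1 = binary.extent
    rows = []
    for _, farm in farms.iterrows():
        fx, fy = float(farm["x"]), float(farm["y"])
        in_extent = x0 <= fx <= x1 and y0 <= fy <= y1
        if not in_extent:
            warnings.warn(f"farm {farm['name']!r} lies outside the raster extent",
                          stacklevel=2)
        r = _buffer_radius_km(float(farm["capacity_mw"]))
        count = 0
        if in_extent:
            count = int(((xs - fx) ** 2 + (ys - fy) ** 2 <= r * r).sum())
        cleared_km2 = cleared_area_ha(float(farm["capacity_mw"])) / 100.0
        rows.append({
            "name": farm["name"], "status": farm["status"],
            "x": fx, "y": fy, "capacity_mw": float(farm["capacity_mw"]),
            "in_extent": in_extent, "buffer_radius_km": r,
            "cleared_km2": cleared_km2,
            "suitable_cells": count,
            "suitable_km2": count * pixel_area_km2,
        })
    per_farm = pd.DataFrame(rows)

    status_rows = []
    for status in STATUSES:
        sub = per_farm[(per_farm["status"] == status) & per_farm["in_extent"]]
        cleared = float(sub["cleared_km2"].sum())
        suitable = float(sub["suitable_km2"].sum())
        # merged-union count: a suitable cell inside any buffer counts once
        merged = 0
        if len(sub) and xs.size:
            inside_any = np.zeros(xs.size, dtype=bool)
            for _, farm in sub.iterrows():
                r = farm["buffer_radius_km"]
                inside_any |= ((xs - farm["x"]) ** 2 + (ys - farm["y"]) ** 2) <= r * r
            merged = int(inside_any.sum())
        status_rows.append({
            "status": status,
            "n_farms": int(len(sub)),
            "cleared_km2": cleared,
            "suitable_km2": suitable,
            "percent_overlap": 100.0 * suitable / cleared if cleared else float("nan"),
            "suitable_km2_merged": merged * pixel_area_km2,
            "percent_overlap_merged":
                100.0 * merged * pixel_area_km2 / cleared if cleared else float("nan"),
        })
    return {"farms": per_farm, "status": pd.DataFrame(status_rows)}
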