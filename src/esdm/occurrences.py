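"""Occurrence-record cleaning and spatial thinning.

Raw occurrence tables (one row per observation: species, lon, lat, date,
basis of record) pass through an ordered filter funnel — record type, missing
coordinates, date range, exact duplicates, equal-coordinate errors, and a
validity mask standing in for sea/out-of-extent checks — and are then thinned
to at most one record per grid cell to blunt spatial autocorrelation. The
default thinning cell is 15 km, a home-range-scale grid for a wide-ranging
ground bird.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import RasterGrid

__all__ = ["CleaningReport", "ThinningGrid", "clean", "thin"]

REQUIRED_COLUMNS = ("species", "lon", "lat")


@dataclass
class CleaningReport:
    """Counts of records removed by each filter, in application order."""

    input_count: int
    removed: dict[str, int] = field(default_factory=dict)
    output_count: int = 0

    def check(self) -> None:
        if sum(self.removed.values()) != self.input_count - self.output_count:
            raise AssertionError("cleaning report does not balance")


@dataclass
class ThinningGrid:
    """Thinning grid: cell size in km, anchored at ``origin``.

    ``crs_note`` must indicate a planar/projected system; thinning geographic
    coordinates by a km grid would be meaningless.
    """

    cell_size: float = 15.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_note: str = "planar"

    def __post_init__(self) -> None:
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")


def _year_of(date_val) -> float:
    if date_val is None or (isinstance(date_val, float) and np.isnan(date_val)):
        return np.nan
    s = str(date_val)
    try:
        return float(s[:4]) if len(s) >= 4 and s[:4].isdigit() else float(s)
    except ValueError:
        return np.nan


def clean(raw: pd.DataFrame, valid_mask: RasterGrid | None = None,
          date_range: tuple[int, int] = (1970, 2024)):
    """Filter a raw occurrence table; returns (cleaned table, CleaningReport).

    Filters, applied in order:

    1. ``non_human_observation`` — keep only human-observation records
       (case/underscore-insensitive match on ``basis_of_record``).
    2. ``missing_coordinates`` — drop rows with NaN lon or lat.
    3. ``out_of_date_range`` — drop rows whose year falls outside
       ``date_range``; rows without a parseable date pass through.
    4. ``duplicate`` — drop exact duplicates of (species, lon, lat, date),
       keeping the first.
    5. ``equal_coordinates`` — drop rows where lon == lat exactly (a classic
       data-entry error signature).
    6. ``outside_valid_area`` — drop rows off the grid or over nodata cells of
       ``valid_mask``.

    An empty result is legal (a warning, not an error).
    """
    if raw.empty:
        raise ValueError("raw occurrence table is empty")
    for col in REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise KeyError(f"occurrence table lacks required column {col!r}")
    df = raw.copy()
    report = CleaningReport(input_count=len(df))

    def apply(name: str, keep: pd.Series) -> None:
        nonlocal df
        report.removed[name] = int((~keep).sum())
        df = df[keep]

    if "basis_of_record" in df.columns:
        basis = df["basis_of_record"].astype(str).str.lower().str.replace("_", " ")
        apply("non_human_observation", basis == "human observation")
    else:
        report.removed["non_human_observation"] = 0

    apply("missing_coordinates",
          df["lon"].notna() & df["lat"].notna())

    if "date" in df.columns:
        years = df["date"].map(_year_of)
        in_range = years.isna() | ((years >= date_range[0]) & (years <= date_range[1]))
        apply("out_of_date_range", in_range)
    else:
        report.removed["out_of_date_range"] = 0

    dup_cols = [c for c in ("species", "lon", "lat", "date") if c in df.columns]
    apply("duplicate", ~df.duplicated(subset=dup_cols, keep="first"))

    apply("equal_coordinates", df["lon"] != df["lat"])

    if valid_mask is not None and len(df):
        row, col = valid_mask.index_of(df["lon"].to_numpy(), df["lat"].to_numpy())
        on_grid = row >= 0
        keep = on_grid.copy()
        keep[on_grid] = valid_mask.mask[row[on_grid], col[on_grid]]
        apply("outside_valid_area", pd.Series(keep, index=df.index))
    else:
        report.removed["outside_valid_area"] = 0

    report.output_count = len(df)
    report.check()
    if df.empty:
        warnings.warn("cleaning removed every record", stacklevel=2)
    return df.reset_index(drop=True), report


def thin(occ: pd.DataFrame, grid: ThinningGrid | None = None, seed: int = 0) -> pd.DataFrame:
    """Retain one record per thinning-grid cell, chosen uniformly at random.

    Cell membership is ``floor((coord - origin) / cell_size)``. The output is
    sorted by cell index, so re-running with the same grid and seed is a fixed
    point (idempotence): each cell already holds a single record.
    """
    grid = grid or ThinningGrid()
    if grid.crs_note.lower() not in {"planar", "projected"}:
        raise ValueError(
            "thinning requires planar/projected coordinates in km; "
            "project geographic coordinates first"
        )
    if occ.empty:
        return occ.copy()
    rng = np.random.default_rng(seed)
    ox, oy = grid.origin
    cx = np.floor((occ["lon"].to_numpy() - ox) / grid.cell_size).astype(int)
    cy = np.floor((occ["lat"].to_numpy() - oy) / grid.cell_size).astype(int)
    df = occ.copy()
    df["_cx"], df["_cy"] = cx, cy
    kept = []
    for _, group in df.sort_values(["_cx", "_cy"], kind="stable").groupby(
            ["_cx", "_cy"], sort=True):
        kept.append(group.index[rng.integers(len(group))])
    out = df.loc[kept].drop(columns=["_cx", "_cy"])
    return out.reset_index(drop=True)
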