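"""Bias-corrected pseudo-absence generation.

True absences are unknown for most occurrence datasets, so pseudo-absences
must be manufactured — and where they are placed decides what the models
learn. The two-step scheme implemented here:

1. **Environmental envelope.** An envelope suitability index scores every
   cell by its standardised distance to the mean conditions at presence
   cells; the study area is split at the median presence-index into a
   high-suitability zone (off limits) and a low-suitability zone (eligible
   for pseudo-absences).
2. **Survey-effort filter.** A survey-effort surface — rasterised counts of
   target-group records put through a 3x3 focal mean — separates "surveyed
   and still absent" cells from merely unvisited ones. Candidate cells must
   carry at least ``effort_floor`` (default 40%) of the maximum observed
   effort; if that starves the candidate pool the floor is relaxed stepwise.

Pseudo-absences are then drawn uniformly from the candidate cells, in
independent replicates, with weights chosen so presences and pseudo-absences
carry equal total weight within each replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GridError, RasterGrid
from .stack import PredictorStack

__all__ = [
    "EnvelopeIndex",
    "SurveyEffort",
    "PresenceAbsenceSet",
    "envelope_index",
    "split_zones",
    "survey_effort",
    "pa_candidates",
    "sample_pseudo_absences",
]


@dataclass
class EnvelopeIndex:
    """Per-cell similarity to the presence environmental envelope.

    ``index = -(1/p) * sum_j |z_j|`` where ``z_j`` standardises layer j by the
    mean and sd observed at presence cells; 0 is the attainable maximum (a
    cell sitting exactly on the presence centroid) and the index is invariant
    to affine rescaling of any input layer.
    """

    surface: RasterGrid
    presence_stats: dict[str, tuple[float, float]]


@dataclass
class SurveyEffort:
    """Smoothed target-group record density and its maximum."""

    surface: RasterGrid
    max_effort: float

    def __post_init__(self) -> None:
        if not self.max_effort > 0:
            raise GridError("survey effort is identically zero")


@dataclass
class PresenceAbsenceSet:
    """Presences (label 1) and pseudo-absences (label 0) with weights.

    ``points`` columns: x, y, label, weight, replicate_id. Within every
    replicate the summed weights of the two classes are equal. ``provenance``
    records the effort floor actually used and candidate-pool sizes, plus a
    ``with_replacement`` flag when the pool could not supply the request even
    at floor 0.
    """

    points: pd.DataFrame
    n_presence: int
    n_pa_per_replicate: int
    provenance: dict = field(default_factory=dict)


def _presence_cells(grid: RasterGrid, presences: pd.DataFrame):
    row, col = grid.index_of(presences["lon"].to_numpy(),
                             presences["lat"].to_numpy())
    ok = row >= 0
    ok[ok] = grid.mask[row[ok], col[ok]]
    return row[ok], col[ok]


def envelope_index(stack: PredictorStack, presences: pd.DataFrame) -> EnvelopeIndex:
    """Envelope suitability index from presence-cell statistics."""
    rows, cols = _presence_cells(stack.template, presences)
    if rows.size < 2:
        raise ValueError("need at least two presences on valid cells")
    stats: dict[str, tuple[float, float]] = {}
    total = np.zeros(stack.template.shape)
    used = 0
    for name, layer in stack.items():
        vals = layer.values[rows, cols]
        mu, sd = float(vals.mean()), float(vals.std())
        if sd <= 0:
            warnings.warn(f"layer {name!r} has zero sd at presences; skipped",
                          stacklevel=2)
            continue
        stats[name] = (mu, sd)
        total += np.abs((layer.values - mu) / sd)
        used += 1
    if used == 0:
        raise ValueError("no layer with positive presence sd")
    index = np.where(stack.mask, -total / used, np.nan)
    return EnvelopeIndex(stack.template.with_values(index), stats)


def split_zones(index: EnvelopeIndex, presences: pd.DataFrame) -> RasterGrid:
    """Binary zone map: 1 = high suitability, 0 = low (pseudo-absence eligible).

    The threshold is the median index at presence cells; cells at or above the
    median are high, strictly below are low.
    """
    grid = index.surface
    rows, cols = _presence_cells(grid, presences)
    if rows.size == 0:
        raise ValueError("no presences on valid cells")
    t = float(np.median(grid.values[rows, cols]))
    zones = np.where(grid.values >= t, 1.0, 0.0)
    zones = np.where(grid.mask, zones, np.nan)
    return grid.with_values(zones)


def survey_effort(target_group: pd.DataFrame, template: RasterGrid,
                  window: int = 3) -> SurveyEffort:
    """Rasterised target-group record counts under a focal mean.

    Edge cells average over the neighbours actually available (partial
    window), so a corner cell is the mean of its 4 in-grid neighbours under
    the default 3x3 window.
    """
    if target_group.empty:
        raise ValueError("target group is empty")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    counts = np.zeros(template.shape)
    row, col = template.index_of(target_group["lon"].to_numpy(),
                                 target_group["lat"].to_numpy())
    ok = row >= 0
    np.add.at(counts, (row[ok], col[ok]), 1.0)
    counts = np.where(template.mask, counts, np.nan)
    kernel = np.ones((window, window))
    filled = np.where(template.mask, counts, 0.0)
    num = ndimage.convolve(filled, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(template.mask.astype(float), kernel,
                           mode="constant", cval=0.0)
    smoothed = np.where(template.mask, num / den, np.nan)
    return SurveyEffort(template.with_values(smoothed), float(np.nanmax(smoothed)))


def pa_candidates(zone_map: RasterGrid, effort: SurveyEffort, floor: float,
                  presence_cells: set[tuple[int, int]]) -> np.ndarray:
    """Boolean candidate-cell map at a given effort floor.

    Candidates are low-zone cells with effort >= floor * max_effort that do
    not hold a presence. Monotone in the floor: lowering it only adds cells.
    """
    eligible = (zone_map.values == 0.0) & zone_map.mask
    eligible &= effort.surface.values >= floor * effort.max_effort
    if presence_cells:
        rows, cols = zip(*presence_cells)
        block = np.zeros(zone_map.shape, dtype=bool)
        block[list(rows), list(cols)] = True
        eligible &= ~block
    return eligible


def sample_pseudo_absences(zone_map: RasterGrid, effort: SurveyEffort,
                           presences: pd.DataFrame, n: int = 10_000,
                           effort_floor: float = 0.40, replicates: int = 3,
                           relax_step: float = 0.05, seed: int = 0) -> PresenceAbsenceSet:
    """Draw ``n`` pseudo-absences per replicate from the filtered low zone.

    The effort floor is relaxed by ``relax_step`` (re-deriving candidates)
    until the pool can supply ``n`` cells or the floor reaches 0; if the pool
    is still short, cells are drawn with replacement and the set is flagged
    as degraded. Presences get weight 1; pseudo-absences get weight
    ``n_presence / n`` so class weight totals match within each replicate.
    """
    if n < 1:
        raise ValueError("n must be positive")
    low_exists = ((zone_map.values == 0.0) & zone_map.mask).any()
    if not low_exists:
        raise ValueError("low-suitability zone is empty")
    prow, pcol = _presence_cells(zone_map, presences)
    presence_cells = set(zip(prow.tolist(), pcol.tolist()))
    n_presence = len(presences)

    floor = effort_floor
    eligible = pa_candidates(zone_map, effort, floor, presence_cells)
    while eligible.sum() < n and floor > 0:
        floor = max(0.0, floor - relax_step)
        eligible = pa_candidates(zone_map, effort, floor, presence_cells)
    with_replacement = bool(eligible.sum() < n)
    if with_replacement:
        warnings.warn(
            f"candidate pool ({int(eligible.sum())}) smaller than n ({n}) even at "
            "floor 0; sampling with replacement", stacklevel=2)
    cand_rows, cand_cols = np.nonzero(eligible)
    if cand_rows.size == 0:
        raise ValueError("no candidate cells even at floor 0")

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(replicates)
    pa_weight = n_presence / n
    frames = []
    for rep in range(1, replicates + 1):
        rng = np.random.default_rng(child_seeds[rep - 1])
        if cand_rows.size == n and not with_replacement:
            pick = np.arange(n)  # exhaustive pool: every candidate is used
        else:
            pick = rng.choice(cand_rows.size, size=n, replace=with_replacement)
        x, y = zone_map.centre_of(cand_rows[pick], cand_cols[pick])
        frames.append(pd.DataFrame({
            "x": presences["lon"].to_numpy(), "y": presences["lat"].to_numpy(),
            "label": 1, "weight": 1.0, "replicate_id": rep,
        }))
        frames.append(pd.DataFrame({
            "x": x, "y": y, "label": 0, "weight": pa_weight, "replicate_id": rep,
        }))
    points = pd.concat(frames, ignore_index=True)
    provenance = {
        "requested_floor": effort_floor,
        "floor_used": floor,
        "candidate_cells": int(cand_rows.size),
        "with_replacement": with_replacement,
        "floors_used": {rep: floor for rep in range(1, replicates + 1)},
    }
    return PresenceAbsenceSet(points, n_presence, n, provenance)
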