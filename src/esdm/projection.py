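"""Future-climate projection and habitat-change classification.

A scenario is a shared socioeconomic pathway (SSP) label, a horizon year and
one or more GCM predictor stacks. Projection averages the GCM stacks into a
consensus climate, predicts ensemble suitability, and binarises at the *same*
threshold as the current map — thresholding current and future maps
differently would conflate threshold drift with climate signal.

Change maps classify each valid cell by its (current, future) binary pair:
stable suitable (1,1), stable unsuitable (0,0), loss (1,0), gain (0,1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridError, RasterGrid
from .models import EnsembleModel, binarise, predict_map
from .stack import PredictorStack, gcm_mean

__all__ = [
    "ScenarioSpec",
    "CHANGE_CLASSES",
    "project_scenario",
    "change_map",
    "change_stats",
]

SSPS = ("SSP1-2.6", "SSP2-4.5", "SSP3-7.0", "SSP5-8.5")

#: Change-map integer codes.
CHANGE_CLASSES = {
    "stable_unsuitable": 0,
    "stable_suitable": 1,
    "loss": 2,
    "gain": 3,
}


@dataclass
class ScenarioSpec:
    """One future scenario: SSP id, horizon year, and its GCM stacks."""

    ssp: str
    year: int
    gcm_stacks: list[PredictorStack]

    def __post_init__(self) -> None:
        if not self.gcm_stacks:
            raise ValueError("scenario needs at least one GCM stack")
        template = self.gcm_stacks[0].template
        for s in self.gcm_stacks[1:]:
            if not s.template.same_grid(template):
                raise GridError("GCM stacks are not co-registered")


def project_scenario(ensemble: EnsembleModel, scenario: ScenarioSpec,
                     threshold: float):
    """(binary map, suitability map) for a scenario.

    GCM stacks are averaged cell-wise first (with one stack the average is the
    identity), then the ensemble is predicted and binarised at ``threshold`` —
    the threshold fitted on the current map.
    """
    consensus = gcm_mean(scenario.gcm_stacks)
    suitability = predict_map(ensemble, consensus)
    return binarise(suitability, threshold), suitability


def change_map(current: RasterGrid, future: RasterGrid) -> RasterGrid:
    """Classify current-vs-future binary suitability per cell.

    Both inputs must be co-registered 0/1 maps; a cell that is nodata in
    either is nodata in the result.
    """
    if not current.same_grid(future):
        raise GridError("current and future maps are not co-registered")
    cur = current.values
    fut = future.values
    out = np.full(cur.shape, np.nan)
    valid = current.mask & future.mask
    cls = np.select(
        [
            (cur == 1) & (fut == 1),
            (cur == 0) & (fut == 0),
            (cur == 1) & (fut == 0),
            (cur == 0) & (fut == 1),
        ],
        [
            CHANGE_CLASSES["stable_suitable"],
            CHANGE_CLASSES["stable_unsuitable"],
            CHANGE_CLASSES["loss"],
            CHANGE_CLASSES["gain"],
        ],
        default=np.nan,
    )
    out[valid] = cls[valid]
    return current.with_values(out)


def change_stats(cm: RasterGrid, pixel_area_km2: float) -> dict[str, float]:
    """Area accounting for a change map.

    Returns km2 per class plus ``net_pct`` = (gain - loss) / current suitable
    x 100, where current suitable = stable suitable + loss. ``net_pct`` is NaN
    when there is no current suitable habitat.
    """
    v = cm.values
    counts = {name: int((v == code).sum()) for name, code in CHANGE_CLASSES.items()}
    out = {f"{name}_km2": n * pixel_area_km2 for name, n in counts.items()}
    current_suitable = counts["stable_suitable"] + counts["loss"]
    future_suitable = counts["stable_suitable"] + counts["gain"]
    out["current_suitable_km2"] = current_suitable * pixel_area_km2
    out["future_suitable_km2"] = future_suitable * pixel_area_km2
    if current_suitable > 0:
        out["net_pct"] = 100.0 * (counts["gain"] - counts["loss"]) / current_suitable
        out["loss_pct"] = 100.0 * counts["loss"] / current_suitable
        out["gain_pct"] = 100.0 * counts["gain"] / current_suitable
    else:
        out["net_pct"] = out["loss_pct"] = out["gain_pct"] = float("nan")
    return out
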