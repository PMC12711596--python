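"""End-to-end orchestration: configuration, seed derivation, and run_all.

The pipeline binds the stages together in their canonical order — clean,
thin, VIF-screen, pseudo-absences, fit algorithms x CV x PA replicates,
TSS-gated ensemble, current prediction, scenario projection and change maps,
zonal and wind-farm overlays — and writes every table, map and seed to a run
directory so a run is reproducible from its manifest.

The default configuration is the study design this package implements:
15 km thinning, 10,000 pseudo-absences x 3 replicates behind a 40% survey-
effort floor, VIF threshold 5, ten algorithms x 3 cross-validation x 3
pseudo-absence replicates (90 runs), 70/30 calibration split, strict TSS >
0.60 ensemble gate, and four SSP scenarios. Two model designs differ only in
the predictor list handed to the VIF screen: a climate-only design
(comparable across scenarios) and an all-variables design.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from .grid import write_ascii_grid
from .models import (ALGORITHMS, build_ensemble, choose_threshold, evaluate,
                     fit, predict_map, binarise, split, variable_importance)
from .occurrences import ThinningGrid, clean, thin
from .overlay import windfarm_overlap, zonal_suitable
from .projection import SSPS, ScenarioSpec, change_map, change_stats, project_scenario
from .pseudoabsence import (envelope_index, sample_pseudo_absences, split_zones,
                            survey_effort)
from .stack import vif_screen
from . import synthetic as synth

__all__ = ["RunConfig", "run_all", "child_seed"]


def child_seed(master: int, stage: str, replicate: int = 0) -> int:
    """Deterministic per-stage seed below 2^31, hashed from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}:{replicate}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """All pipeline settings; the defaults are the reference study design."""

    seed: int = 0
    # occurrence prep
    thin_cell_km: float = 15.0
    date_range: tuple[int, int] = (1970, 2024)
    # pseudo-absences
    pa_n: int = 10_000
    pa_replicates: int = 3
    effort_floor: float = 0.40
    relax_step: float = 0.05
    # predictors
    vif_threshold: float = 5.0
    predictors: list[str] | None = None  # None = all stack layers
    # modelling
    algorithms: tuple[str, ...] = ALGORITHMS
    train_fraction: float = 0.70
    cv_replicates: int = 3
    tss_cutoff: float = 0.60
    # scenarios / overlays
    scenario_years: tuple[int, ...] = (2050, 2070)
    ssps: tuple[str, ...] = SSPS
    pixel_area_km2: float | None = None  # None = cell_size**2
    # synthetic world: 100x100 cells of 3 km, so the 15 km thinning grid is
    # 5x5 cells and a 1,000-record sample thins to a few hundred presences
    landscape: synth.LandscapeSpec = field(default_factory=lambda: synth.LandscapeSpec(
        extent=(0.0, 0.0, 300.0, 300.0), cell_size=3.0, n_predictors=5))
    n_presences: int = 1000
    n_target_species: int = 19
    n_per_target_species: int = 200
    n_zones: int = 4
    n_farms: int = 20
    n_gcms: int = 5
    gcm_noise_sd: float = 0.05
    scenario_delta_scale: float = 0.15  # per-SSP shift step on the first layer

    def validate(self) -> None:
        checks = [
            self.thin_cell_km > 0, 1 <= self.pa_n, self.pa_replicates >= 1,
            0 <= self.effort_floor <= 1, self.relax_step > 0,
            self.vif_threshold > 1, 0 < self.train_fraction < 1,
            self.cv_replicates >= 1, -1 <= self.tss_cutoff <= 1,
            len(self.algorithms) >= 1,
        ]
        if not all(checks):
            raise ValueError("invalid RunConfig settings")
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms: {sorted(unknown)}")


def _synthetic_world(cfg: RunConfig) -> dict:
    """Generate every input the pipeline needs, from the config's seeds."""
    spec = cfg.landscape
    stack = synth.make_stack(spec)
    names = stack.names
    # strong logistic signal on the first three layers, rest are noise:
    # steep enough that suitability is close to 0/1 over most of the map and
    # parameter recovery is identifiable from a presence/pseudo-absence sample
    coefs = {names[0]: 6.0}
    if len(names) > 1:
        coefs[names[1]] = -4.5
    if len(names) > 2:
        coefs[names[2]] = 3.0
    # a rare species: the negative intercept keeps suitable habitat to a
    # minority of the landscape, so the envelope low zone is mostly genuine
    truth = synth.make_truth(stack, coefs, intercept=-2.5)
    bias = synth.make_bias(stack.template, kind="smooth",
                           seed=child_seed(cfg.seed, "bias"))
    presences = synth.sample_presences(
        truth, bias, cfg.n_presences, seed=child_seed(cfg.seed, "presences"))
    surrogates = synth.make_surrogate_truths(
        stack, cfg.n_target_species, seed=child_seed(cfg.seed, "surrogates"))
    target = synth.make_target_group(
        surrogates, bias, cfg.n_target_species, cfg.n_per_target_species,
        seed=child_seed(cfg.seed, "target_group"))
    deltas = {}
    for k, ssp in enumerate(cfg.ssps):
        for year in cfg.scenario_years:
            shift = -cfg.scenario_delta_scale * (k + 1) * (
                1.0 if year == min(cfg.scenario_years) else 1.4)
            deltas[f"{ssp}_{year}"] = {names[0]: shift}
    futures = synth.make_futures(
        stack, deltas, n_gcms=cfg.n_gcms, gcm_noise_sd=cfg.gcm_noise_sd,
        seed=child_seed(cfg.seed, "futures"), smoothness=spec.smoothness)
    zones = synth.make_zones(spec.extent, cfg.n_zones,
                             seed=child_seed(cfg.seed, "zones"))
    farms = synth.make_windfarms(spec.extent, cfg.n_farms,
                                 seed=child_seed(cfg.seed, "windfarms"))
    return {
        "stack": stack, "truth": truth, "bias": bias, "presences": presences,
        "target_group": target, "futures": futures, "zones": zones,
        "farms": farms, "coefficients": coefs,
    }


def run_all(cfg: RunConfig, out_dir, world: dict | None = None) -> dict:
    """Execute the full pipeline and write outputs under ``out_dir``.

    ``world`` may supply pre-built inputs (stack, presences, target_group,
    futures, zones, farms); when omitted, the synthetic generator builds them
    from the config. Returns the run manifest (also written as JSON).
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {"config": _jsonable(asdict(cfg)), "stages": {}}

    def log(stage: str, **info) -> None:
        manifest["stages"][stage] = {"elapsed_s": round(time.time() - t0, 3), **info}

    world = world or _synthetic_world(cfg)
    stack = world["stack"]
    pixel_area = cfg.pixel_area_km2 or stack.template.cell_size ** 2
    log("inputs", n_layers=len(stack), n_raw_presences=len(world["presences"]))

    # 1. occurrence prep -----------------------------------------------------
    cleaned, report = clean(world["presences"], stack.template, cfg.date_range)
    thinned = thin(cleaned, ThinningGrid(cfg.thin_cell_km,
                                         (stack.template.x_min, stack.template.y_min)),
                   seed=child_seed(cfg.seed, "thin"))
    cleaned_tg, _ = clean(world["target_group"], stack.template, cfg.date_range)
    thinned.to_csv(out / "presences_thinned.csv", index=False)
    log("occurrence_prep", removed=report.removed, n_clean=len(cleaned),
        n_thinned=len(thinned))

    # 2. predictor screening -------------------------------------------------
    model_stack = stack.subset(cfg.predictors) if cfg.predictors else stack
    vif_report, screened = vif_screen(
        model_stack, threshold=cfg.vif_threshold, seed=child_seed(cfg.seed, "vif"))
    log("vif_screen", dropped=vif_report.dropped,
        retained={k: round(v, 3) for k, v in vif_report.retained.items()})

    # 3. pseudo-absences -----------------------------------------------------
    env = envelope_index(screened, thinned)
    zones_map = split_zones(env, thinned)
    effort = survey_effort(cleaned_tg, stack.template)
    pa_set = sample_pseudo_absences(
        zones_map, effort, thinned, n=cfg.pa_n, effort_floor=cfg.effort_floor,
        replicates=cfg.pa_replicates, relax_step=cfg.relax_step,
        seed=child_seed(cfg.seed, "pseudo_absence"))
    pa_set.points.to_csv(out / "presence_absence.csv", index=False)
    log("pseudo_absence", **pa_set.provenance)

    # 4. model fitting: algorithms x cv x pa ---------------------------------
    features = screened.names
    runs, run_rows = [], []
    all_tests = []
    for pa_rep in range(1, cfg.pa_replicates + 1):
        data = pa_set.points[pa_set.points["replicate_id"] == pa_rep].copy()
        feats = pd.DataFrame(
            screened.values_at(data["x"].to_numpy(), data["y"].to_numpy()),
            columns=features, index=data.index)
        data = pd.concat([data, feats], axis=1).dropna(subset=features)
        splits = split(data, cfg.train_fraction, cfg.cv_replicates,
                       seed=child_seed(cfg.seed, "split", pa_rep))
        for cv_rep, (train, test) in enumerate(splits, start=1):
            all_tests.append(test)
            for alg in cfg.algorithms:
                run = fit(alg, train, features,
                          seed=child_seed(cfg.seed, f"fit_{alg}",
                                          pa_rep * 100 + cv_rep))
                run.pa_replicate, run.cv_replicate = pa_rep, cv_rep
                evaluate(run, test)
                runs.append(run)
                run_rows.append({
                    "algorithm": alg, "pa_rep": pa_rep, "cv_rep": cv_rep,
                    **{k: run.eval[k] for k in
                       ("auc", "tss", "optimal_threshold")},
                })
    runs_table = pd.DataFrame(run_rows)
    runs_table.to_csv(out / "runs.csv", index=False)
    log("fit", n_runs=len(runs))

    # 5. ensemble + current map ----------------------------------------------
    ensemble = build_ensemble(runs, cfg.tss_cutoff)
    validation = pd.concat(all_tests, ignore_index=True)
    threshold = choose_threshold(ensemble, validation)
    suitability = predict_map(ensemble, screened)
    current_binary = binarise(suitability, threshold)
    write_ascii_grid(suitability, out / "suitability_current.asc")
    write_ascii_grid(current_binary, out / "binary_current.asc")
    importance = variable_importance(ensemble, validation,
                                     seed=child_seed(cfg.seed, "importance"))
    importance.rename("importance_pct").to_csv(out / "variable_importance.csv")
    log("ensemble", n_members=len(ensemble.members), threshold=threshold,
        member_tss=[round(m.tss, 3) for m in ensemble.members])

    # 6. scenarios ------------------------------------------------------------
    scenario_rows = []
    for name, gcm_stacks in world["futures"].items():
        ssp, year = name.rsplit("_", 1)
        screened_futures = [s.subset(features) for s in gcm_stacks]
        scen = ScenarioSpec(ssp, int(year), screened_futures)
        future_binary, _ = project_scenario(ensemble, scen, threshold)
        cm = change_map(current_binary, future_binary)
        stats = change_stats(cm, pixel_area)
        write_ascii_grid(cm, out / f"change_{name}.asc")
        scenario_rows.append({"scenario": ssp, "year": int(year), **stats})
    scenarios_table = pd.DataFrame(scenario_rows)
    scenarios_table.to_csv(out / "scenario_changes.csv", index=False)
    log("projection", n_scenarios=len(scenario_rows))

    # 7. overlays --------------------------------------------------------------
    zonal = zonal_suitable(current_binary, world["zones"], pixel_area)
    zonal.to_csv(out / "zonal_suitable.csv", index=False)
    farms_tables = windfarm_overlap(current_binary, world["farms"], pixel_area)
    farms_tables["farms"].to_csv(out / "windfarm_farms.csv", index=False)
    farms_tables["status"].to_csv(out / "windfarm_status.csv", index=False)
    vio.write_zones_geojson(world["zones"], out / "zones.geojson")
    vio.write_windfarms_geojson(world["farms"], out / "windfarms.geojson")
    log("overlay", n_zones=len(zonal), n_farms=len(farms_tables["farms"]))

    manifest["n_runs"] = len(runs)
    manifest["threshold"] = threshold
    manifest["pixel_area_km2"] = pixel_area
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
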