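"""Generate bias-corrected pseudo-absences.

Two-step scheme: (1) an envelope suitability index splits the study area at
the median presence index into high/low-suitability zones; (2) a survey-effort
layer from target-group records filters the low zone to cells carrying at
least 40% of the maximum effort (relaxed stepwise if the pool runs short).
"""

import warnings

from esdm import (LandscapeSpec, envelope_index, make_bias, make_stack,
                  make_surrogate_truths, make_target_group, make_truth,
                  sample_presences, sample_pseudo_absences, split_zones,
                  survey_effort)

warnings.filterwarnings("ignore")

spec = LandscapeSpec(extent=(0, 0, 300, 300), cell_size=3.0, n_predictors=5,
                     seed=1)
stack = make_stack(spec)
truth = make_truth(stack, {"env01": 6.0, "env02": -4.5, "env03": 3.0}, -2.5)
bias = make_bias(stack.template, kind="blocks", low=0.5)
presences = sample_presences(truth, bias, 500, seed=2)
surrogates = make_surrogate_truths(stack, n_species=19, seed=3)
target_group = make_target_group(surrogates, bias, 19, 200, seed=4)

env = envelope_index(stack, presences)
zones = split_zones(env, presences)
low_frac = float((zones.values == 0).mean())
print(f"envelope split: {low_frac:.0%} of cells are low-suitability "
      "(pseudo-absence eligible)")

effort = survey_effort(target_group, stack.template)
print(f"survey effort from {len(target_group)} target-group records; "
      f"max smoothed effort {effort.max_effort:.2f} records/cell")

pa = sample_pseudo_absences(zones, effort, presences, n=2000, replicates=3,
                            seed=5)
prov = pa.provenance
print(f"effort floor: requested {prov['requested_floor']:.2f}, "
      f"used {prov['floor_used']:.2f} after relaxation; "
      f"{prov['candidate_cells']} candidate cells")
pts = pa.points
for rep, grp in pts.groupby("replicate_id"):
    w1 = grp.loc[grp.label == 1, "weight"].sum()
    w0 = grp.loc[grp.label == 0, "weight"].sum()
    print(f"  replicate {rep}: {(grp.label == 0).sum()} PAs, "
          f"class weight totals {w1:.1f} vs {w0:.1f}")
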