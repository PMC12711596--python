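"""Zonal suitable-area accounting and wind-farm footprint overlap.

Zonal statistics assign each cell to the polygon containing its centre.
Wind-farm footprints are circular buffers sized from installed capacity at
0.3 ha/MW; overlap counts the suitable cells whose centres fall inside.
"""

import warnings

import numpy as np

from esdm import (binarise, choose_threshold, make_windfarms, make_zones,
                  pixel_area_km2_from_arcsec, predict_map, windfarm_overlap,
                  zonal_suitable)
from esdm.benchmark import strong_signal_benchmark
from esdm.grid import RasterGrid

warnings.filterwarnings("ignore")

bench = strong_signal_benchmark(seed=1)
threshold = choose_threshold(bench.ensemble, bench.validation)
binary = binarise(predict_map(bench.ensemble, bench.stack), threshold)
pixel_km2 = bench.stack.template.cell_size ** 2

zones = make_zones((0, 0, 300, 300), 4, seed=1)
table = zonal_suitable(binary, zones, pixel_km2)
print("suitable habitat per zone:")
for _, row in table.iterrows():
    print(f"  {row.zone}: {row.suitable_km2:8.0f} km2 "
          f"({row.percent_suitable:5.1f}% of the zone)")
total = table["suitable_km2"].sum()
print(f"  zones sum to {total:.0f} km2 = whole-map figure "
      f"{(binary.values == 1).sum() * pixel_km2:.0f} km2 (exact partition)")

# a finer grid so cleared footprints span multiple pixels
fine = RasterGrid(np.kron(binary.values, np.ones((6, 6))), 0.0, 300.0, 0.5)
farms = make_windfarms((0, 0, 300, 300), 12, capacity_range_mw=(200, 2500),
                       seed=2)
out = windfarm_overlap(fine, farms, pixel_area_km2=0.25)
print("\nwind-farm overlap by development status:")
for _, row in out["status"].iterrows():
    print(f"  {row.status:18s} {row.n_farms:2d} farms, "
          f"cleared {row.cleared_km2:6.2f} km2, "
          f"suitable within buffers {row.suitable_km2:6.2f} km2 "
          f"({row.percent_overlap:5.1f}%)")
print(f"\n(30 arc-second pixel area used with real rasters: "
      f"{pixel_area_km2_from_arcsec(30.0):.4f} km2)")
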