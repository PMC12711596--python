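"""Clean a raw occurrence table and thin it to one record per 15-km cell.

The cleaning report is the record-count funnel: how many rows each filter
removed, in order. Thinning then blunts spatial autocorrelation by keeping a
single (seeded-random) record per grid cell.
"""

import numpy as np
import pandas as pd

from esdm import ThinningGrid, clean, thin
from esdm.grid import RasterGrid

rng = np.random.default_rng(0)
n = 400
raw = pd.DataFrame({
    "species": "focal",
    "lon": rng.uniform(0, 150, n),
    "lat": rng.uniform(0, 150, n),
    "date": rng.integers(1950, 2025, n).astype(str),
    "basis_of_record": rng.choice(
        ["human observation", "preserved specimen"], n, p=[0.9, 0.1]),
})
raw.loc[5, "lon"] = np.nan                      # a missing coordinate
raw.loc[10, ["lon", "lat"]] = 42.0, 42.0        # an equal-coordinate error

land = RasterGrid(np.zeros((150, 150)), 0.0, 150.0, 1.0)
land.values[:, 140:] = np.nan                   # a sea strip

cleaned, report = clean(raw, valid_mask=land, date_range=(1970, 2024))
print(f"input records: {report.input_count}")
for step, removed in report.removed.items():
    print(f"  -{removed:3d}  {step}")
print(f"cleaned records: {report.output_count}")

thinned = thin(cleaned, ThinningGrid(cell_size=15.0), seed=1)
print(f"thinned to {len(thinned)} records "
      f"(one per occupied 15 km x 15 km cell)")
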