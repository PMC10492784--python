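"""Biogeographic regionalization and MST spatial standardization.

Two planted faunas with disjoint genus pools are binned on a geodesic
hexagonal grid; PAM on the modified-Forbes dissimilarity and modularity
communities on the co-occurrence network should both recover the split.
Then per-bin occurrence sets with very different spatial footprints are
standardized to the median minimum-spanning-tree length.
"""

import numpy as np
import pandas as pd

from paleodiv.spatial import HexGrid, hex_bin, mst_standardize, regionalize

rng = np.random.default_rng(7)
grid = HexGrid(2)

rows = []
for fauna, (lat0, lon0) in enumerate([(20.0, 30.0), (-30.0, -120.0)]):
    for g in range(40):
        for _ in range(12):
            rows.append(dict(genus=f"G{fauna}_{g}",
                             paleolat=float(np.clip(lat0 + rng.normal(0, 8), -89, 89)),
                             paleolng=float(lon0 + rng.normal(0, 8))))
occurrences = pd.DataFrame(rows)

matrix = hex_bin(occurrences, grid=grid)
assignment = regionalize(matrix)
print(f"occupied cells: {len(matrix.cell_ids)}")
print(f"PAM regions (k={assignment.k_pam}, silhouette "
      f"{assignment.silhouette:.2f}): {np.bincount(assignment.region_pam)}")
print(f"network communities: {np.bincount(assignment.region_network)}")
print(f"method agreement (adjusted Rand): {assignment.agreement_ari:.2f}")

per_bin = {}
for b in range(4):
    n = 40 + 60 * b
    per_bin[b] = pd.DataFrame(dict(
        genus="x",
        paleolat=np.clip(rng.normal(10, 4 + 7 * b, n), -89, 89),
        paleolng=rng.normal(40, 5 + 10 * b, n)))
_, audit = mst_standardize(per_bin, grid, threshold="median")
print("\nMST standardization audit (km):")
print(audit.round(0).to_string(index=False))
# Both clusterings agree perfectly on the planted split; after
# standardization every bin's MST length sits at or below the median
# threshold, equalizing the spatial footprint across time bins.
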