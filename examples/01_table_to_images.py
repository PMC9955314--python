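"""Convert a synthetic clinical table into grayscale cell images.

Simulates a PIMA-like table (768 records, 500 negative / 268 positive),
ranks the features with ReliefF, builds the 120x120 importance-ordered
layout and rasterizes every record.
"""

import numpy as np

import tabraster as tr
from tabraster.layout import convert_rows

table = tr.simulate_table(tr.SimSpec(seed=0))
print(f"table: {table.n_samples} records x {table.n_features} features, "
      f"classes {np.bincount(table.labels)}")

normalized = tr.minmax_normalize(table)  # each feature -> [0, 1]
weights = tr.relieff_weights(table, k=10)
print(weights.to_frame().sort_values("rank").to_string(index=False))

ranking = tr.rank_features(weights)
layout = tr.build_layout(ranking, "rank-based", 120, 120)
print("cell areas (px), most important first:",
      [int(a) for a in layout.areas()[ranking]])

images = convert_rows(normalized, layout)
print(f"{len(images)} images of {images[0].shape}; "
      f"first record intensities span {images[0].pixels.min()}"
      f"-{images[0].pixels.max()}")
# The rank-1 feature owns the largest cell; each cell's brightness is its
# normalized feature value x 255, so bright cells mean high measurements.
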