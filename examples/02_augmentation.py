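"""Quintuple an image set with the four affine augmentation techniques.

Each original contributes a reflected, rotated (±30°), rescaled (0.9–1.1)
and translated (±10 px) copy, all label-preserving.
"""

import numpy as np

import tabraster as tr
from tabraster.layout import convert_rows

table = tr.simulate_table(tr.SimSpec(n_per_class=(40, 24), seed=0))
normalized = tr.minmax_normalize(table)
layout = tr.build_layout(
    tr.rank_features(tr.relieff_weights(table, k=5)), "rank-based", 120, 120
)
images = convert_rows(normalized, layout)

augmented, meta = tr.augment_dataset(images, tr.AugmentConfig(seed=0))
labels = np.array([img.label for img in augmented])
print(f"{len(images)} originals -> {len(augmented)} images "
      f"({(labels == 0).sum()} negative / {(labels == 1).sum()} positive)")
for m in meta[:5]:
    print(m["technique"], m["params"])
# Output counts are exactly 5x the input, per class; the printed parameters
# are the uniform draws from each technique's configured range.
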