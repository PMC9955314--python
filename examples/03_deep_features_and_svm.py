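"""Extract deep features from both backbones, fuse, select and classify.

Runs at a reduced scale (small table, 32x32 backbone input, frozen random
backbones) so it finishes in well under a minute on one CPU; the feature
dimensions (512 + 2048 = 2560, top-100 selected here) are unchanged by the
input resolution thanks to the global average pool.
"""

import numpy as np

import tabraster as tr
from tabraster.backbone import stack_images
from tabraster.layout import convert_rows

table = tr.simulate_table(tr.SimSpec(n_per_class=(60, 40), seed=0))
normalized = tr.minmax_normalize(table)
layout = tr.build_layout(
    tr.rank_features(tr.relieff_weights(table, k=5)), "rank-based", 40, 40
)
images = convert_rows(normalized, layout)
x = stack_images(images, size=32)
y = np.array([img.label for img in images])

m18 = tr.adapt_backbone(18, seed=0)
m50 = tr.adapt_backbone(50, seed=0)
fused = tr.fuse(tr.extract_features(m18, x), tr.extract_features(m50, x))
print(f"fused deep features: {fused.shape[0]} rows x {fused.shape[1]} columns")

idx = np.random.default_rng(0).permutation(len(y))
train_idx, test_idx = idx[:80], idx[80:]
res = tr.selected_fusion_classify(
    fused, y, train_idx, test_idx, n_select=100, kernel="cubic",
    relieff_k=5, relieff_m=60, seed=0,
)
print(f"selected {len(res.selected)} of {fused.shape[1]} columns")
print("confusion:", res.confusion)
print({k: round(v, 4) for k, v in res.report.as_dict().items()})
# accuracy is on the 0-100 scale; specificity/precision/sensitivity/F1 are
# proportions and MCC is in [-1, 1] (1 = perfect, 0 = chance).
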