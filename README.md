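# tabraster

Turn small numeric clinical tables into grayscale images so that 2-D
convolutional models — and CNN-feature + SVM hybrids — can classify them.

Many clinical datasets are tables of a few bounded measurements per
patient (the reference schema here is the PIMA diabetes collection: eight
features such as glucose, BMI and age, plus a binary outcome, for 768
records). `tabraster` maps each record to a 120×120 grayscale image in
which every feature owns a rectangular cell: cell **area** follows the
feature's ReliefF importance rank and cell **brightness** is the min–max
normalized value × 255. The images can then be augmented with affine
transforms (reflection, rotation, scale, translation; 5× the data) and
classified three ways:

1. fine-tuned residual networks of depth 18 and 50 (implemented in-package
   in plain numpy, with a penultimate feature tap);
2. a kernel SVM on the fused 512 + 2048 = 2560-dimensional deep features;
3. a kernel SVM on the ReliefF top-500 of those fused features.

The ReliefF weight of feature A accumulates, over visited samples R with
k nearest hits H (same class) and misses M (other class),

    W(A) += mean diff(A, R, M)/m − mean diff(A, R, H)/m,
    diff(A, I1, I2) = |value(A,I1) − value(A,I2)| / (max(A) − min(A)),

and the evaluation reports tp/tn/fp/fn with accuracy (×100), specificity,
precision, sensitivity, F1 and the Matthews correlation coefficient.

## Worked example

```python
import numpy as np
import tabraster as tr
from tabraster.layout import convert_rows

table = tr.simulate_table(tr.SimSpec(seed=0))   # 768 PIMA-like records
weights = tr.relieff_weights(table, k=10)
print(weights.to_frame().sort_values("rank").head(4).to_string(index=False))
```

prints

```
feature_name   weight  rank
     glucose 0.042158     1
         bmi 0.040682     2
 pregnancies 0.032989     3
         age 0.029332     4
```

— the four features the generator makes informative are ranked first.
Continuing,

```python
layout = tr.build_layout(tr.rank_features(weights), "rank-based", 120, 120)
images = convert_rows(tr.minmax_normalize(table), layout)
augmented, meta = tr.augment_dataset(images, tr.AugmentConfig(seed=0))
print(len(images), "->", len(augmented))        # 768 -> 3840
```

the 768 rasters become 3840 images (2500 negative / 1340 positive), and a
scaled-down select-then-classify run (`examples/03_deep_features_and_svm.py`)
ends with

```
fused deep features: 100 rows x 2560 columns
selected 100 of 2560 columns
{'accuracy': 70.0, 'specificity': 0.8, 'precision': 0.75,
 'sensitivity': 0.6, 'f1_score': 0.6667, 'mcc': 0.4082}
```

accuracy is a percentage of the held-out images; MCC is in [−1, 1] with 0
meaning chance. The `examples/` directory has one short script per
capability, and the `tabraster` command exposes `simulate`, `convert`,
`augment`, `run` and `replicate` subcommands. Results on the real PIMA
table require a user-supplied CSV (`tabraster replicate pima.csv`), which
prints the achieved metrics next to the published reference values.

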