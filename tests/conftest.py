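import numpy as np
import pytest

import tabraster as tr
from tabraster.layout import convert_rows

# Ten reference rows of the PIMA schema (features + outcome), used as a
# known-good CSV fixture across modules.
PIMA_SAMPLE_ROWS = """pregnancies,glucose,blood_pressure,skin_thickness,insulin,bmi,pedigree,age,outcome
1,89,66,23,94,28.1,0.167,21,0
2,197,70,45,543,30.5,0.158,53,1
1,189,60,23,846,30.1,0.398,59,1
1,103,30,38,83,43.3,0.183,33,0
9,171,110,24,240,45.4,0.721,54,1
5,88,66,21,23,24.4,0.342,30,0
2,141,58,34,128,25.4,0.699,24,0
2,100,66,20,90,32.9,0.867,28,1
7,83,78,26,71,29.3,0.767,36,0
7,160,54,32,175,30.5,0.588,39,1
"""


@pytest.fixture
def pima_csv(tmp_path):
    path = tmp_path / "pima_sample.csv"
    path.write_text(PIMA_SAMPLE_ROWS)
    return path


@pytest.fixture
def pima_table(pima_csv):
    return tr.read_table(pima_csv)


@pytest.fixture(scope="session")
def small_table():
    """64-row synthetic table, both classes populated."""
    return tr.simulate_table(tr.SimSpec(n_per_class=(40, 24), seed=7))


@pytest.fixture(scope="session")
def small_images(small_table):
    norm = tr.minmax_normalize(small_table)
    wv = tr.relieff_weights(small_table, k=5)
    layout = tr.build_layout(tr.rank_features(wv), "rank-based", 40, 40)
    return convert_rows(norm, layout)


@pytest.fixture(scope="session")
def sixteen_images():
    table = tr.simulate_table(tr.SimSpec(n_per_class=(8, 8), seed=3))
    norm = tr.minmax_normalize(table)
    wv = tr.relieff_weights(table, k=2)
    layout = tr.build_layout(tr.rank_features(wv), "rank-based", 40, 40)
    return convert_rows(norm, layout)


@pytest.fixture(scope="session")
def image_batch_32(sixteen_images):
    x = np.stack([tr.preprocess(img, size=32) for img in sixteen_images])
    y = np.array([img.label for img in sixteen_images])
    return x, y
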