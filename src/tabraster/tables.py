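"""Reading, validating and normalizing numeric feature tables.

The reference schema is the PIMA Indians Diabetes table: eight clinical /
physical measurements per record plus a binary ``outcome`` column
(0 = non-diabetic, 1 = diabetic). Each feature carries a declared
physiological range (e.g. glucose 0–199 mg/dL) against which min–max
normalization is performed, so that every feature lands in [0, 1] before
being rasterized into a grayscale cell image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "NormalizedTable",
    "PIMA_FEATURES",
    "PIMA_BOUNDS",
    "read_table",
    "minmax_normalize",
]

#: Feature names of the PIMA reference schema, in column order.
PIMA_FEATURES: tuple[str, ...] = (
    "pregnancies",
    "glucose",
    "blood_pressure",
    "skin_thickness",
    "insulin",
    "bmi",
    "pedigree",
    "age",
)

#: Declared (xmin, xmax) per PIMA feature: the published ranges of the dataset.
PIMA_BOUNDS: dict[str, tuple[float, float]] = {
    "pregnancies": (0.0, 17.0),
    "glucose": (0.0, 199.0),
    "blood_pressure": (0.0, 122.0),
    "skin_thickness": (0.0, 99.0),
    "insulin": (0.0, 846.0),
    "bmi": (0.0, 67.1),
    "pedigree": (0.078, 2.42),
    "age": (21.0, 81.0),
}

#: Default name of the label column in CSV files.
LABEL_COLUMN = "outcome"


@dataclass
class FeatureTable:
    """An n×p numeric matrix with binary labels and optional declared bounds.

    Parameters
    ----------
    values : ndarray of shape (n, p)
        Raw feature values.
    feature_names : sequence of str, length p
    labels : ndarray of shape (n,)
        Binary outcomes, 0 (negative class) or 1 (positive class).
    bounds : dict mapping feature name -> (xmin, xmax), optional
        Declared per-feature ranges; required for ``bounds_mode="declared"``
        normalization.
    """

    values: np.ndarray
    feature_names: tuple[str, ...]
    labels: np.ndarray
    bounds: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.feature_names = tuple(self.feature_names)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if p < 1:
            raise ValueError("no features: table must have p >= 1 columns")
        if n < 2:
            raise ValueError("table must have at least 2 rows")
        if len(self.feature_names) != p:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {p} columns"
            )
        if self.labels.shape != (n,):
            raise ValueError("labels must be a vector with one entry per row")
        lab = np.unique(self.labels)
        if not np.all(np.isin(lab, [0, 1])):
            raise ValueError(f"labels must be binary 0/1, found {lab}")
        self.labels = self.labels.astype(int)
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at row {bad[0]}, "
                f"feature '{self.feature_names[bad[1]]}' (missing values are "
                "not imputed; clean the table first)"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def bounds_array(self) -> np.ndarray:
        """Declared bounds as a (p, 2) array, in feature order."""
        if self.bounds is None:
            raise ValueError("table carries no declared bounds")
        return np.array([self.bounds[f] for f in self.feature_names], float)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df[LABEL_COLUMN] = self.labels
        return df


@dataclass
class NormalizedTable:
    """Min–max normalized view of a :class:`FeatureTable` (all values in [0,1])."""

    values: np.ndarray
    source: FeatureTable
    bounds_used: np.ndarray = field(repr=False, default=None)  # (p, 2)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise ValueError("normalized values must lie in [0, 1]")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return self.source.feature_names

    @property
    def labels(self) -> np.ndarray:
        return self.source.labels


def read_table(
    path,
    schema: tuple[str, ...] | None = None,
    label_column: str = LABEL_COLUMN,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> FeatureTable:
    """Read a CSV feature table with a binary label column.

    Parameters
    ----------
    path : str or path-like
        CSV file with a header row.
    schema : tuple of str, optional
        Expected feature names. When given, the header must contain exactly
        these columns plus the label column; when omitted the schema is
        inferred as every non-label column. If the schema equals the PIMA
        reference schema and no bounds are supplied, the published PIMA
        ranges are attached automatically.
    label_column : str
        Name of the outcome column (default ``"outcome"``).
    bounds : dict, optional
        Declared per-feature ranges to attach to the table.
    """
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise ValueError(
            f"label column '{label_column}' not found in {list(df.columns)}"
        )
    feature_cols = [c for c in df.columns if c != label_column]
    if not feature_cols:
        raise ValueError("no features: table contains only the label column")
    if schema is not None:
        if tuple(feature_cols) != tuple(schema):
            raise ValueError(
                f"header {feature_cols} does not match expected schema {list(schema)}"
            )
    if len(df) == 0:
        raise ValueError("empty table")
    feats = df[feature_cols]
    numeric = feats.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric or missing value at row {r}, column '{feature_cols[c]}'"
        )
    if bounds is None and tuple(feature_cols) == PIMA_FEATURES:
        bounds = dict(PIMA_BOUNDS)
    return FeatureTable(
        values=numeric.to_numpy(dtype=float),
        feature_names=tuple(feature_cols),
        labels=df[label_column].to_numpy(),
        bounds=bounds,
    )


def minmax_normalize(
    table: FeatureTable, bounds_mode: str = "declared"
) -> NormalizedTable:
    """Rescale every feature to [0, 1] via x̂ = (x − xmin) / (xmax − xmin).

    ``bounds_mode="declared"`` uses the table's declared per-feature ranges
    (values outside the range are clipped to [0, 1] after the transform, so
    the downstream 0–255 raster contract always holds).
    ``bounds_mode="observed"`` uses each column's observed min/max, in which
    case every column attains both 0 and 1 exactly.
    """
    if bounds_mode == "declared":
        if table.bounds is None:
            raise ValueError(
                "bounds_mode='declared' requires declared bounds on the table"
            )
        b = table.bounds_array()
    elif bounds_mode == "observed":
        b = np.stack(
            [table.values.min(axis=0), table.values.max(axis=0)], axis=1
        )
    else:
        raise ValueError(f"unknown bounds_mode {bounds_mode!r}")

    span = b[:, 1] - b[:, 0]
    if np.any(span <= 0):
        idx = int(np.argmax(span <= 0))
        raise ValueError(
            f"feature '{table.feature_names[idx]}' has xmax <= xmin "
            f"({b[idx, 1]} <= {b[idx, 0]}): constant features cannot be "
            "min-max normalized"
        )
    xhat = (table.values - b[:, 0]) / span
    if bounds_mode == "declared":
        xhat = np.clip(xhat, 0.0, 1.0)
    return NormalizedTable(values=xhat, source=table, bounds_used=b)
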