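"""ReliefF feature weighting for binary-labelled numeric tables.

ReliefF scores each feature by how well it separates a sample from its
nearest *misses* (nearest neighbors of the other class) relative to its
nearest *hits* (same class). For a visited sample R, feature A and neighbor
sets H (k hits) and M (k misses), the weight update is

    W(A) <- W(A) + mean_diff(A, R, M)/m - mean_diff(A, R, H)/m

with the per-feature difference

    diff(A, I1, I2) = |value(A, I1) - value(A, I2)| / (max(A) - min(A)).

At k = 1 this is exactly the classical single-hit/single-miss Relief update;
the k-neighbor form averages diff over the k hits and k misses. Neighbors
are found by Manhattan distance over the same diff terms. Weights are
bounded in [-1, 1] by construction.

The same routine serves both uses in the pipeline: ranking raw clinical
features to size layout cells, and re-selecting the top columns of fused
deep-feature matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import FeatureTable

__all__ = [
    "WeightVector",
    "attribute_diff",
    "relieff_weights",
    "rank_features",
    "select_top",
]


@dataclass
class WeightVector:
    """Per-feature ReliefF importance weights W(A)."""

    weights: np.ndarray
    k: int
    m: int | str
    seed: int | None = None
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise ValueError("weights must be a vector")
        if np.any(np.abs(self.weights) > 1.0 + 1e-12):
            raise ValueError("ReliefF weights must lie in [-1, 1]")

    def __len__(self) -> int:
        return self.weights.size

    def to_frame(self) -> pd.DataFrame:
        """Weights as a (feature_name, weight, rank) table, rank 1 = best."""
        order = rank_features(self)
        rank = np.empty(len(self), dtype=int)
        rank[order] = np.arange(1, len(self) + 1)
        names = self.feature_names or tuple(
            f"f{i}" for i in range(1, len(self) + 1)
        )
        return pd.DataFrame(
            {"feature_name": names, "weight": self.weights, "rank": rank}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def attribute_diff(value_a: float, value_b: float, bounds) -> float:
    """Normalized per-feature difference |a − b| / (max − min), in [0, 1]."""
    lo, hi = float(bounds[0]), float(bounds[1])
    if hi - lo <= 0:
        raise ValueError(f"zero feature span: bounds ({lo}, {hi})")
    return abs(float(value_a) - float(value_b)) / (hi - lo)


def _as_matrix(table, labels, bounds):
    if isinstance(table, FeatureTable):
        X = table.values
        y = table.labels
        b = (
            table.bounds_array()
            if table.bounds is not None
            else np.stack([X.min(axis=0), X.max(axis=0)], axis=1)
        )
    else:
        X = np.asarray(table, dtype=float)
        if labels is None:
            raise ValueError("labels are required with a plain matrix")
        y = np.asarray(labels, dtype=int)
        if bounds is None:
            b = np.stack([X.min(axis=0), X.max(axis=0)], axis=1)
        else:
            b = np.asarray(bounds, dtype=float)
    return X, y, b


def relieff_weights(
    table,
    labels=None,
    *,
    k: int = 10,
    m: int | str = "all",
    seed: int | None = None,
    bounds=None,
) -> WeightVector:
    """Compute ReliefF weights for a binary-labelled feature matrix.

    Parameters
    ----------
    table : FeatureTable or array of shape (n, p)
        When a plain matrix is given, ``labels`` must be supplied; diff
        denominators default to each column's observed min/max unless
        ``bounds`` (shape (p, 2)) is given. Constant columns (zero span)
        receive weight exactly 0.
    k : int
        Number of nearest hits and misses averaged per visited sample.
    m : "all" or int
        Samples visited. ``"all"`` visits every sample once in row order
        (deterministic); an integer draws m samples without replacement
        using ``seed``.
    seed : int, optional
        RNG seed for subsampled visits; ignored when ``m="all"``.

    Returns
    -------
    WeightVector
        Weights in [-1, 1], one per feature.
    """
    X, y, b = _as_matrix(table, labels, bounds)
    n, p = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"binary labels required, found classes {classes}")
    if counts.min() < k + 1:
        small = classes[int(np.argmin(counts))]
        raise ValueError(
            f"class {small} has only {counts.min()} samples; k={k} nearest "
            f"hits need at least k+1 per class — use a smaller k"
        )

    span = b[:, 1] - b[:, 0]
    live = span > 0  # constant features contribute diff = 0 everywhere
    Z = np.zeros_like(X)
    Z[:, live] = (X[:, live] - b[live, 0]) / span[live]

    if m == "all":
        visited = np.arange(n)
    else:
        m_int = int(m)
        if not 1 <= m_int <= n:
            raise ValueError(f"m must be in [1, {n}], got {m}")
        rng = np.random.default_rng(seed)
        visited = np.sort(rng.choice(n, size=m_int, replace=False))
    m_eff = visited.size

    W = np.zeros(p)
    same = y[:, None] == y[None, :]
    for i in visited:
        d = np.abs(Z - Z[i]).sum(axis=1)  # Manhattan over diff terms
        hit_mask = same[i].copy()
        hit_mask[i] = False
        miss_mask = ~same[i]
        # stable argsort -> distance ties broken by ascending sample index
        hits = np.flatnonzero(hit_mask)[
            np.argsort(d[hit_mask], kind="stable")[:k]
        ]
        misses = np.flatnonzero(miss_mask)[
            np.argsort(d[miss_mask], kind="stable")[:k]
        ]
        W += np.abs(Z[misses] - Z[i]).mean(axis=0) / m_eff
        W -= np.abs(Z[hits] - Z[i]).mean(axis=0) / m_eff

    names = (
        table.feature_names if isinstance(table, FeatureTable) else None
    )
    return WeightVector(
        weights=W, k=k, m=m if m == "all" else int(m), seed=seed,
        feature_names=names,
    )


def rank_features(weights: WeightVector | np.ndarray) -> np.ndarray:
    """Feature indices sorted by descending weight (0-based).

    Ties are broken by ascending feature index, so equal weights yield the
    identity order.
    """
    w = weights.weights if isinstance(weights, WeightVector) else np.asarray(weights)
    # stable sort on -w keeps ascending index order within ties
    return np.argsort(-w, kind="stable")


def select_top(weights: WeightVector | np.ndarray, n: int) -> np.ndarray:
    """The first ``n`` entries of :func:`rank_features` (0-based indices)."""
    order = rank_features(weights)
    if not 1 <= n <= order.size:
        raise ValueError(f"n must be in [1, {order.size}], got {n}")
    return order[:n]
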