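"""Deep-feature fusion, kernel-SVM classification and evaluation metrics.

Approach 2 of the pipeline concatenates the 512-dim depth-18 and 2048-dim
depth-50 penultimate features into a 2560-column fused matrix and
classifies it with a binary SVM (linear, quadratic, cubic or Gaussian
kernel). Approach 3 first re-weights the fused columns with ReliefF on the
training rows and keeps the top 500 before classifying.

Evaluation reports the confusion matrix (positive class = 1) and six
derived statistics:

    accuracy    = (tp + tn) / (tp + fp + tn + fn) × 100
    specificity = tn / (tn + fp)
    precision   = tp / (tp + fp)
    sensitivity = tp / (tp + fn)
    F1          = 2 tp / (2 tp + fp + fn)
    MCC         = (tp·tn − fn·fp) / sqrt((tp+fn)(tn+fp)(tp+fp)(tn+fn))

A zero denominator makes the corresponding metric NaN and records its name
in ``MetricsReport.undefined`` rather than silently reporting 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .relieff import relieff_weights, select_top

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "KERNELS",
    "fuse",
    "train_svm",
    "evaluate",
    "selected_fusion_classify",
    "SelectionResult",
]

KERNELS = ("linear", "quadratic", "cubic", "gaussian")


@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Six confusion-matrix statistics; accuracy on the 0–100 scale."""

    accuracy: float
    specificity: float
    precision: float
    sensitivity: float
    f1_score: float
    mcc: float
    undefined: tuple[str, ...] = field(default=())

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "specificity": self.specificity,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "f1_score": self.f1_score,
            "mcc": self.mcc,
        }


def fuse(features_a: np.ndarray, features_b: np.ndarray) -> np.ndarray:
    """Column-wise concatenation of two feature matrices, a's columns first.

    Rows must correspond to the same images in the same (manifest) order.
    """
    a = np.asarray(features_a)
    b = np.asarray(features_b)
    if a.shape[0] != b.shape[0]:
        raise ValueError(
            f"row mismatch: {a.shape[0]} vs {b.shape[0]} samples"
        )
    return np.hstack([a, b])


def train_svm(
    features: np.ndarray,
    labels: np.ndarray,
    kernel: str = "cubic",
    C: float = 1.0,
    gamma: float | None = None,
    seed: int = 0,
) -> Pipeline:
    """Fit a binary kernel SVM on z-scored features.

    Kernels: ``linear``; ``quadratic``/``cubic`` = polynomial of degree 2/3
    with unit coefficient and offset 1; ``gaussian`` = radial basis with
    kernel width sqrt(p) (i.e. gamma = 1/p) unless overridden. Features are
    standardized with training-set statistics inside the fitted pipeline.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    if kernel == "linear":
        svc = SVC(kernel="linear", C=C, random_state=seed)
    elif kernel in ("quadratic", "cubic"):
        deg = 2 if kernel == "quadratic" else 3
        svc = SVC(kernel="poly", degree=deg, gamma=1.0, coef0=1.0, C=C,
                  random_state=seed)
    elif kernel == "gaussian":
        g = gamma if gamma is not None else 1.0 / X.shape[1]
        svc = SVC(kernel="rbf", gamma=g, C=C, random_state=seed)
    else:
        raise ValueError(f"unknown kernel {kernel!r}; choose from {KERNELS}")
    clf = Pipeline([("scale", StandardScaler()), ("svm", svc)])
    clf.fit(X, y)
    return clf


def evaluate(predictions, truth) -> tuple[ConfusionMatrix, MetricsReport]:
    """Confusion matrix and the six statistics for binary label vectors."""
    pred = np.asarray(predictions).astype(int)
    y = np.asarray(truth).astype(int)
    if pred.shape != y.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {y.shape}")
    for v in (pred, y):
        if not np.all(np.isin(v, [0, 1])):
            raise ValueError("labels must be binary 0/1")
    cm = ConfusionMatrix(
        tp=int(np.sum((pred == 1) & (y == 1))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
    )
    return cm, metrics_from_confusion(cm)


def _ratio(num: float, den: float, name: str, undefined: list) -> float:
    if den == 0:
        undefined.append(name)
        return float("nan")
    return num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    undefined: list[str] = []
    accuracy = _ratio(tp + tn, cm.total, "accuracy", undefined) * 100.0
    specificity = _ratio(tn, tn + fp, "specificity", undefined)
    precision = _ratio(tp, tp + fp, "precision", undefined)
    sensitivity = _ratio(tp, tp + fn, "sensitivity", undefined)
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "f1_score", undefined)
    mcc_den = math.sqrt(
        float(tp + fn) * float(tn + fp) * float(tp + fp) * float(tn + fn)
    )
    mcc = _ratio(tp * tn - fn * fp, mcc_den, "mcc", undefined)
    return MetricsReport(
        accuracy=accuracy,
        specificity=specificity,
        precision=precision,
        sensitivity=sensitivity,
        f1_score=f1,
        mcc=mcc,
        undefined=tuple(undefined),
    )


@dataclass
class SelectionResult:
    """Outcome of select-then-classify on fused features."""

    report: MetricsReport
    confusion: ConfusionMatrix
    selected: np.ndarray  # column indices kept, ReliefF rank order
    classifier: Pipeline


def selected_fusion_classify(
    fused: np.ndarray,
    labels: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    n_select: int = 500,
    kernel: str = "cubic",
    seed: int = 0,
    relieff_k: int = 10,
    relieff_m: int | str = "all",
    selection_on: str = "train",
) -> SelectionResult:
    """ReliefF-select the top fused columns, then train and evaluate an SVM.

    By default the ReliefF weights are computed on the training rows only
    (leakage-safe) with observed per-column min/max as diff denominators;
    ``selection_on="all"`` reproduces a selection over every row instead.
    ``n_select`` equal to the fused dimension makes the selection the
    identity, recovering the no-selection classifier exactly.
    """
    X = np.asarray(fused, dtype=float)
    y = np.asarray(labels).astype(int)
    if not 1 <= n_select <= X.shape[1]:
        raise ValueError(
            f"n_select must be in [1, {X.shape[1]}], got {n_select}"
        )
    if selection_on == "train":
        sel_rows = np.asarray(train_idx)
    elif selection_on == "all":
        sel_rows = np.arange(X.shape[0])
    else:
        raise ValueError(f"unknown selection_on {selection_on!r}")
    wv = relieff_weights(
        X[sel_rows], y[sel_rows], k=relieff_k, m=relieff_m, seed=seed
    )
    cols = select_top(wv, n_select)
    clf = train_svm(X[np.asarray(train_idx)][:, cols], y[np.asarray(train_idx)],
                    kernel=kernel, seed=seed)
    pred = clf.predict(X[np.asarray(test_idx)][:, cols])
    cm, report = evaluate(pred, y[np.asarray(test_idx)])
    return SelectionResult(report=report, confusion=cm, selected=cols,
                           classifier=clf)
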