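"""Synthetic clinical tables and toy prediction pairs for testing.

The generator emulates the statistical skeleton of the PIMA diabetes
records: eight bounded numeric features, a 500:268 negative:positive class
imbalance (768 rows), and class-conditional Gaussian features where an
informative subset carries a standardized mean shift between classes.
Feature values are clipped to the declared physiological bounds.

What it deliberately does *not* emulate: the real dataset's inter-feature
correlations, zero-inflation of insulin/skin-thickness, or any non-Gaussian
shape — it exists so that every pipeline stage (normalization, ReliefF
ranking, rasterization, augmentation, deep features, SVM) is exercisable
and its recovery properties provable without external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tables import PIMA_BOUNDS, PIMA_FEATURES, FeatureTable

__all__ = ["SimSpec", "simulate_table", "toy_confusion"]


@dataclass
class SimSpec:
    """Parameters of the class-conditional Gaussian table generator.

    Defaults are the reference study conditions: 500 negative / 268
    positive rows, the eight PIMA features with their published bounds, a
    clinically plausible informative subset (glucose, BMI, age,
    pregnancies) and a moderate standardized effect size of 1.0. Per-feature
    noise defaults to range/6 so that ±3 s.d. spans the declared bounds;
    class-0 means sit at the bound midpoints.
    """

    n_per_class: tuple[int, int] = (500, 268)
    feature_names: tuple[str, ...] = PIMA_FEATURES
    bounds: dict = field(default_factory=lambda: dict(PIMA_BOUNDS))
    informative: tuple[int, ...] = (1, 5, 7, 0)  # glucose, bmi, age, pregnancies
    effect_size: float = 1.0
    noise_sd: np.ndarray | None = None
    seed: int = 0

    @property
    def p(self) -> int:
        return len(self.feature_names)


def simulate_table(spec: SimSpec | None = None) -> FeatureTable:
    """Draw a synthetic feature table from a :class:`SimSpec`.

    Class-conditional Gaussian per feature: class 0 is centered at the
    bound midpoint; class 1 is shifted by ``effect_size × noise_sd`` on the
    informative features only. Values are clipped to the declared bounds
    (clipping never changes the label counts). Deterministic per seed; rows
    are ordered class 0 first.
    """
    spec = spec or SimSpec()
    n0, n1 = spec.n_per_class
    if n0 < 1 or n1 < 1:
        raise ValueError("each class needs at least one sample")
    effects = np.asarray(spec.effect_size, dtype=float)
    if not np.all(np.isfinite(effects)):
        raise ValueError("effect sizes must be finite")
    if np.any(effects != 0) and len(spec.informative) == 0:
        raise ValueError(
            "nonzero effect size requested but the informative set is empty"
        )
    b = np.array([spec.bounds[f] for f in spec.feature_names], dtype=float)
    span = b[:, 1] - b[:, 0]
    sd = (
        span / 6.0
        if spec.noise_sd is None
        else np.broadcast_to(np.asarray(spec.noise_sd, float), (spec.p,))
    )
    mu0 = b.mean(axis=1)
    shift = np.zeros(spec.p)
    shift[list(spec.informative)] = np.broadcast_to(
        effects, (len(spec.informative),)
    ) * sd[list(spec.informative)]
    rng = np.random.default_rng(spec.seed)
    x0 = rng.normal(mu0, sd, size=(n0, spec.p))
    x1 = rng.normal(mu0 + shift, sd, size=(n1, spec.p))
    values = np.clip(np.vstack([x0, x1]), b[:, 0], b[:, 1])
    labels = np.concatenate([np.zeros(n0, int), np.ones(n1, int)])
    return FeatureTable(
        values=values,
        feature_names=spec.feature_names,
        labels=labels,
        bounds=dict(spec.bounds),
    )


def toy_confusion(kind: str, n: int, seed: int = 0):
    """Deterministic prediction/truth pairs for metric tests.

    ``perfect`` predicts the truth exactly (MCC 1), ``inverted`` flips every
    label (MCC −1), ``random`` predicts independently of the truth (MCC
    near 0). Truth is an even 0/1 mix shuffled by the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    truth = np.arange(n) % 2
    rng.shuffle(truth)
    if kind == "perfect":
        pred = truth.copy()
    elif kind == "inverted":
        pred = 1 - truth
    elif kind == "random":
        pred = rng.integers(0, 2, size=n)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return pred, truth
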