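"""Backbone adaptation, preprocessing, fine-tuning and feature extraction.

Wraps the numpy residual networks behind the four operations the pipeline
needs: build a depth-18 or depth-50 backbone with a two-layer classification
head, resize grayscale cell images to the backbone input resolution,
fine-tune with SGD + momentum (batch 32, 5 epochs, initial learning rate
0.001, drop factor 0.1 every 20 epochs by default), and tap the pooled
penultimate features (512 dimensions at depth 18, 2048 at depth 50).

Pretrained initialization requires a locally supplied ``.npz`` weights file
(nothing is ever downloaded); random He initialization is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .layout import GrayImage
from .nn import ResNet, SGDMomentum, fit

__all__ = ["TrainConfig", "adapt_backbone", "preprocess", "train", "extract_features"]

#: Per-channel statistics commonly used with pretrained image stems.
_STEM_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
_STEM_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass
class TrainConfig:
    """Fine-tuning hyperparameters (defaults are the study settings)."""

    batch_size: int = 32
    max_epochs: int = 5
    initial_lr: float = 0.001
    lr_drop_factor: float = 0.1
    lr_drop_period: int = 20
    momentum: float = 0.9
    train_fraction: float = 0.8
    seed: int = 0


def adapt_backbone(
    depth: int,
    n_classes: int = 2,
    pretrained: bool = False,
    weights_path=None,
    hidden: int = 64,
    seed: int = 0,
    dtype=np.float32,
) -> ResNet:
    """Build a residual backbone with a fresh two-layer classification head.

    ``depth`` must be 18 (512-dim features) or 50 (2048-dim features).
    ``pretrained=True`` loads body weights from a local ``.npz`` file
    produced by ``ResNet.state_dict``; no network access is ever attempted.
    """
    model = ResNet(depth, n_classes=n_classes, hidden=hidden, seed=seed,
                   dtype=dtype)
    if pretrained:
        if weights_path is None:
            raise ValueError(
                "pretrained=True needs a local weights_path (.npz); no "
                "download source is configured"
            )
        with np.load(weights_path) as f:
            model.load_state_dict(dict(f))
    return model


def preprocess(
    image: GrayImage | np.ndarray,
    size: int = 224,
    mode: str = "unit",
) -> np.ndarray:
    """Resize a grayscale image and replicate it to 3 channels.

    Bilinear resize to ``size``×``size``, grayscale replicated across the
    three stem channels, shaped (3, size, size) float32. ``mode="unit"``
    maps 8-bit intensities to [0, 1]; ``mode="stem-stats"`` additionally
    standardizes each channel with the conventional pretrained-stem
    statistics (for use with pretrained weights).
    """
    px = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    if px.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {px.shape}")
    x = px.astype(np.float32) / 255.0
    if px.shape != (size, size):
        x = _sk_resize(x, (size, size), order=1, anti_aliasing=False,
                       preserve_range=True).astype(np.float32)
    out = np.repeat(x[None, :, :], 3, axis=0)
    if mode == "stem-stats":
        out = (out - _STEM_MEAN[:, None, None]) / _STEM_STD[:, None, None]
    elif mode != "unit":
        raise ValueError(f"unknown preprocessing mode {mode!r}")
    return out


def stack_images(
    images: list[GrayImage], size: int = 224, mode: str = "unit"
) -> np.ndarray:
    """Preprocess a list of images into one (n, 3, size, size) batch array."""
    return np.stack([preprocess(img, size=size, mode=mode) for img in images])


def train(
    model: ResNet,
    x: np.ndarray,
    y: np.ndarray,
    config: TrainConfig | None = None,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    verbose: bool = False,
) -> dict:
    """Fine-tune a backbone in-place; returns per-epoch accuracy/loss curves."""
    config = config or TrainConfig()
    opt = SGDMomentum(
        model.params(),
        lr=config.initial_lr,
        momentum=config.momentum,
        drop_factor=config.lr_drop_factor,
        drop_period=config.lr_drop_period,
    )
    return fit(
        model, x, y,
        epochs=config.max_epochs,
        batch_size=config.batch_size,
        optimizer=opt,
        x_val=x_val, y_val=y_val,
        seed=config.seed,
        verbose=verbose,
    )


def extract_features(
    model: ResNet, x: np.ndarray, batch_size: int = 64
) -> np.ndarray:
    """Pooled penultimate features, (n, feature_dim), manifest row order.

    Deterministic for fixed weights; an empty input yields a
    (0, feature_dim) matrix.
    """
    if x.shape[0] == 0:
        return np.zeros((0, model.feature_dim), dtype=np.float32)
    chunks = [
        model.forward_features(x[i : i + batch_size])
        for i in range(0, x.shape[0], batch_size)
    ]
    return np.concatenate(chunks, axis=0)
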