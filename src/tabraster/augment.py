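"""Affine data augmentation for cell-structured grayscale images.

Four label-preserving geometric transforms enlarge the image set five-fold:
each original contributes itself plus one reflected, one rotated, one
rescaled and one translated copy. Parameter ranges follow the study
defaults: rotation uniform in [-30, 30] degrees, isotropic scale uniform in
[0.9, 1.1], translation uniform integers in [-10, 10] pixels per axis, and
reflection is a parameter-free left-right flip. Regions moved off-canvas
are filled with 0 (black); interpolation is bilinear, with a final
round-half-up cast back to 8 bits.

Photometric transforms are deliberately excluded: brightness encodes the
feature values, so changing it would corrupt the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import AffineTransform, rotate, warp

from .layout import GrayImage

__all__ = ["AugmentConfig", "TECHNIQUES", "augment_image", "augment_dataset"]

TECHNIQUES = ("reflection", "rotation", "scale", "translation")


@dataclass
class AugmentConfig:
    """Parameter ranges for the four augmentation techniques."""

    rotation_deg: tuple[float, float] = (-30.0, 30.0)
    scale: tuple[float, float] = (0.9, 1.1)
    translation_px: tuple[int, int] = (-10, 10)
    seed: int = 0
    techniques: tuple[str, ...] = field(default=TECHNIQUES)


def draw_params(technique: str, config: AugmentConfig, rng: np.random.Generator):
    """Draw one parameter set for a technique from its configured range."""
    if technique == "reflection":
        return {}
    if technique == "rotation":
        return {"angle_deg": float(rng.uniform(*config.rotation_deg))}
    if technique == "scale":
        return {"factor": float(rng.uniform(*config.scale))}
    if technique == "translation":
        lo, hi = config.translation_px
        return {
            "tx": int(rng.integers(lo, hi + 1)),
            "ty": int(rng.integers(lo, hi + 1)),
        }
    raise ValueError(f"unknown augmentation technique {technique!r}")


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    return np.clip(np.floor(arr + 0.5), 0, 255).astype(np.uint8)


def augment_image(
    image: GrayImage,
    technique: str,
    rng: np.random.Generator | None = None,
    params: dict | None = None,
    config: AugmentConfig | None = None,
) -> GrayImage:
    """Apply one augmentation technique to an 8-bit grayscale image.

    Parameters are drawn from ``config`` ranges using ``rng`` unless given
    explicitly via ``params`` (useful for identity checks: angle 0, scale 1
    or shift (0, 0) reproduce the input pixel-for-pixel).
    """
    if technique not in TECHNIQUES:
        raise ValueError(f"unknown augmentation technique {technique!r}")
    if params is None:
        if rng is None:
            raise ValueError("either params or rng must be provided")
        params = draw_params(technique, config or AugmentConfig(), rng)

    src = image.pixels.astype(float)
    h, w = src.shape
    if technique == "reflection":
        out = src[:, ::-1]
    elif technique == "rotation":
        out = rotate(
            src, params["angle_deg"], order=1, cval=0.0, preserve_range=True
        )
    elif technique == "scale":
        s = params["factor"]
        if s == 1.0:
            out = src
        else:
            # zoom about the image center: dst = s * (src - c) + c
            cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
            tform = AffineTransform(
                scale=(s, s), translation=(cx - s * cx, cy - s * cy)
            )
            out = warp(
                src, tform.inverse, order=1, cval=0.0, preserve_range=True
            )
    else:  # translation by integer pixels, exact
        tx, ty = params["tx"], params["ty"]
        out = np.zeros_like(src)
        xs_src = slice(max(0, -tx), min(w, w - tx))
        ys_src = slice(max(0, -ty), min(h, h - ty))
        xs_dst = slice(max(0, tx), min(w, w + tx))
        ys_dst = slice(max(0, ty), min(h, h + ty))
        out[ys_dst, xs_dst] = src[ys_src, xs_src]

    return GrayImage(pixels=_to_uint8(out), label=image.label)


def augment_dataset(
    images: list[GrayImage], config: AugmentConfig | None = None
) -> tuple[list[GrayImage], list[dict]]:
    """Quintuple an image set: original + one copy per technique.

    Output order is, for each input image in turn: the original followed by
    its reflection, rotation, scale and translation variants. Labels are
    inherited. Deterministic for a fixed ``config.seed``.

    Returns
    -------
    (images, metadata)
        ``metadata[i]`` records the source index, technique ("original" for
        pass-throughs) and drawn parameters of output image i.
    """
    if not images:
        raise ValueError("augment_dataset requires a non-empty image set")
    config = config or AugmentConfig()
    rng = np.random.default_rng(config.seed)
    out: list[GrayImage] = []
    meta: list[dict] = []
    for idx, img in enumerate(images):
        out.append(img)
        meta.append({"source_index": idx, "technique": "original", "params": {}})
        for tech in config.techniques:
            params = draw_params(tech, config, rng)
            out.append(augment_image(img, tech, params=params))
            meta.append(
                {"source_index": idx, "technique": tech, "params": params}
            )
    return out, meta
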