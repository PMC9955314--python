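"""Importance-ordered cell layouts and grayscale rasterization.

Each tabular record becomes one small grayscale image: every feature owns a
rectangular cell on a fixed canvas (120×120 by default) and the cell's
brightness encodes the normalized feature value (value × 255). Cell sizes
follow feature importance — the top-ranked feature gets the largest cell —
so that convolutional models see the most informative measurements at the
largest spatial scale.

The cell geometry is a deterministic guillotine (edge-to-edge) slicing of
the canvas: features are visited in importance order, and each slices a
strip off the longer side of the remaining rectangle, with strip thickness
proportional to its importance mass. The resulting partition is exact (no
background pixels), area-ordered, and asymmetric under mirroring for two or
more unequally-weighted features — asymmetry matters because reflected
augmented copies must remain distinguishable from their originals.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .tables import NormalizedTable

__all__ = ["CellLayout", "GrayImage", "build_layout", "rasterize", "convert_dataset"]


def _round_half_up(x):
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass
class GrayImage:
    """An 8-bit single-channel raster with an optional class label."""

    pixels: np.ndarray
    label: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be a 2-D uint8 array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def save(self, path) -> None:
        Image.fromarray(self.pixels, mode="L").save(path, format="PNG")


@dataclass
class CellLayout:
    """Partition of a canvas into one rectangle per feature.

    ``cells[i]`` is the half-open rectangle ``(x0, y0, x1, y1)`` owned by
    feature ``i`` (0-based feature indexing; pixel (x, y) belongs to the cell
    iff x0 <= x < x1 and y0 <= y < y1). ``ranking`` is the importance order
    (0-based feature indices, most important first) the layout was built from.
    """

    width: int
    height: int
    cells: list[tuple[int, int, int, int]]
    ranking: np.ndarray

    @property
    def n_features(self) -> int:
        return len(self.cells)

    def areas(self) -> np.ndarray:
        return np.array(
            [(x1 - x0) * (y1 - y0) for x0, y0, x1, y1 in self.cells]
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "width": self.width,
                "height": self.height,
                "cells": [list(c) for c in self.cells],
                "ranking": [int(r) for r in self.ranking],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CellLayout":
        d = json.loads(text)
        return cls(
            width=d["width"],
            height=d["height"],
            cells=[tuple(c) for c in d["cells"]],
            ranking=np.array(d["ranking"], dtype=int),
        )

    def layout_hash(self) -> str:
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:12]

    def mirrored(self, axis: str = "horizontal") -> set:
        """Cell set under a left-right or top-bottom mirror of the canvas."""
        out = set()
        for x0, y0, x1, y1 in self.cells:
            if axis == "horizontal":
                out.add((self.width - x1, y0, self.width - x0, y1))
            else:
                out.add((x0, self.height - y1, x1, self.height - y0))
        return out


def build_layout(
    ranking,
    masses="rank-based",
    width: int = 120,
    height: int = 120,
) -> CellLayout:
    """Slice a width×height canvas into one cell per feature.

    Parameters
    ----------
    ranking : sequence of int
        Permutation of 0..p-1, most important feature first (as produced by
        :func:`tabraster.relieff.rank_features`).
    masses : "rank-based" or sequence of positive reals
        Relative target areas, aligned with *ranking order*. The default
        assigns masses p, p-1, ..., 1 along the ranking, so areas decrease
        with importance regardless of the sign of the underlying weights.
    """
    ranking = np.asarray(ranking, dtype=int)
    p = ranking.size
    if sorted(ranking.tolist()) != list(range(p)):
        raise ValueError("ranking must be a permutation of 0..p-1")
    if width < p or height < p:
        raise ValueError(
            f"canvas {width}x{height} too small for {p} features "
            "(need width, height >= p)"
        )
    if isinstance(masses, str):
        if masses != "rank-based":
            raise ValueError(f"unknown masses mode {masses!r}")
        mass = np.arange(p, 0, -1, dtype=float)
    else:
        mass = np.asarray(masses, dtype=float)
        if mass.size != p:
            raise ValueError("need one mass per feature")
        if np.any(mass <= 0):
            raise ValueError("masses must be strictly positive")

    cells: dict[int, tuple[int, int, int, int]] = {}
    x0, y0, x1, y1 = 0, 0, width, height
    remaining_mass = float(mass.sum())
    for step, feat in enumerate(ranking):
        n_left = p - step - 1  # features still waiting after this one
        if n_left == 0:
            cells[int(feat)] = (x0, y0, x1, y1)
            break
        w, h = x1 - x0, y1 - y0
        vertical = w >= h  # slice off the longer side; ties -> vertical cut
        extent = w if vertical else h
        t = int(_round_half_up(extent * mass[step] / remaining_mass))
        t = max(1, min(t, extent - n_left))
        if t < 1 or extent - t < n_left:
            raise ValueError("canvas too small for the requested layout")
        if vertical:
            cells[int(feat)] = (x0, y0, x0 + t, y1)
            x0 += t
        else:
            cells[int(feat)] = (x0, y0, x1, y0 + t)
            y0 += t
        remaining_mass -= mass[step]

    return CellLayout(
        width=width,
        height=height,
        cells=[cells[i] for i in range(p)],
        ranking=ranking,
    )


def rasterize(row, layout: CellLayout, label: int | None = None) -> GrayImage:
    """Paint one normalized record onto the layout.

    Every pixel of feature i's cell is set to round-half-up(255 × row[i]).
    """
    row = np.asarray(row, dtype=float)
    if row.shape != (layout.n_features,):
        raise ValueError(
            f"row has {row.size} values but layout has {layout.n_features} cells"
        )
    if row.min() < 0.0 or row.max() > 1.0:
        raise ValueError("row values must be normalized to [0, 1]")
    img = np.zeros((layout.height, layout.width), dtype=np.uint8)
    intensities = _round_half_up(255.0 * row).astype(np.uint8)
    for i, (x0, y0, x1, y1) in enumerate(layout.cells):
        img[y0:y1, x0:x1] = intensities[i]
    return GrayImage(pixels=img, label=label)


def convert_rows(table: NormalizedTable, layout: CellLayout) -> list[GrayImage]:
    """Rasterize every row of a normalized table (in memory, row order)."""
    labels = table.labels
    return [
        rasterize(table.values[i], layout, label=int(labels[i]))
        for i in range(table.values.shape[0])
    ]


def convert_dataset(
    table: NormalizedTable, layout: CellLayout, out_dir
) -> list[dict]:
    """Rasterize a table to PNG files plus a JSON manifest.

    Writes ``sample_00000.png`` ... and ``manifest.json`` mapping each file
    to its source row index, label and the layout hash. Returns the manifest
    entries. Deterministic: re-running with identical inputs produces
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lh = layout.layout_hash()
    manifest = []
    for i, img in enumerate(convert_rows(table, layout)):
        name = f"sample_{i:05d}.png"
        img.save(out / name)
        manifest.append(
            {"file": name, "row_index": i, "label": img.label, "layout_hash": lh}
        )
    (out / "layout.json").write_text(layout.to_json())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
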