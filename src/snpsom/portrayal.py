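"""Grid portraits of allele scores and their ternary rendering.

A portrait is the SOM grid with each unit valued by the mean *raw* allele
score (0-2 scale) of its member SNPs for one individual, or the element-wise
mean over a group.  Units without member SNPs are filled by iterated
8-neighbor means so the image is contiguous.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Sequence

import numpy as np
from PIL import Image

from .genotype_io import AlleleMatrix
from .som import SomModel

__all__ = [
    "Portrait",
    "ColorMap",
    "individual_portrait",
    "portrait_stack",
    "mean_portrait",
    "difference_portrait",
    "render",
    "fill_empty_units",
]


@dataclasses.dataclass
class Portrait:
    grid: np.ndarray
    subject: str
    kind: str = "individual"  # individual | mean | difference

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        lo, hi = (-2.0, 2.0) if self.kind == "difference" else (0.0, 2.0)
        if self.grid.size and (self.grid.min() < lo - 1e-9 or self.grid.max() > hi + 1e-9):
            raise ValueError(f"{self.kind} portrait values outside [{lo}, {hi}]")

    @property
    def flat(self) -> np.ndarray:
        return self.grid.ravel()


def fill_empty_units(values: np.ndarray, filled: np.ndarray) -> np.ndarray:
    """Fill empty grid cells by iterated means over filled 8-neighbors.

    ``values``: rows x cols x ... array; ``filled``: rows x cols bool mask.
    Cells gaining at least one filled neighbor are set each sweep, until no
    empty cell remains (the grid is connected, so this terminates).
    """
    values = np.array(values, dtype=float)
    filled = filled.copy()
    if filled.all():
        return values
    if not filled.any():
        raise ValueError("cannot fill a grid with no observed units")
    shifts = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    while not filled.all():
        acc = np.zeros_like(values)
        cnt = np.zeros(filled.shape, dtype=float)
        for dr, dc in shifts:
            shifted_v = np.roll(values, (dr, dc), axis=(0, 1))
            shifted_f = np.roll(filled, (dr, dc), axis=(0, 1))
            # mask wrap-around rows/cols introduced by roll
            valid = np.ones(filled.shape, dtype=bool)
            if dr == 1:
                valid[0, :] = False
            elif dr == -1:
                valid[-1, :] = False
            if dc == 1:
                valid[:, 0] = False
            elif dc == -1:
                valid[:, -1] = False
            use = shifted_f & valid
            acc[use] += shifted_v[use]
            cnt += use
        newly = ~filled & (cnt > 0)
        values[newly] = acc[newly] / cnt[newly][..., None] if values.ndim == 3 else acc[newly] / cnt[newly]
        filled |= newly
    return values


def _unit_values(model: SomModel, matrix: AlleleMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(K x M unit mean raw scores, K bool occupied mask)."""
    k = model.n_units
    sums = np.zeros((k, matrix.n_samples))
    np.add.at(sums, model.assignment, matrix.scores.astype(float))
    counts = np.bincount(model.assignment, minlength=k).astype(float)
    occupied = counts > 0
    sums[occupied] /= counts[occupied, None]
    return sums, occupied


def portrait_stack(model: SomModel, matrix: AlleleMatrix) -> dict[str, Portrait]:
    """Individual portraits for every sample (vectorized; shared fill)."""
    rows, cols = model.config.rows, model.config.cols
    values, occupied = _unit_values(model, matrix)
    cube = values.reshape(rows, cols, matrix.n_samples)
    cube = fill_empty_units(cube, occupied.reshape(rows, cols))
    return {
        sid: Portrait(grid=cube[:, :, j], subject=sid, kind="individual")
        for j, sid in enumerate(matrix.sample_ids)
    }


def individual_portrait(model: SomModel, matrix: AlleleMatrix, sample: str) -> Portrait:
    """Portrait of one individual: per-unit mean raw allele score."""
    sample_ids = list(matrix.sample_ids)
    if sample not in sample_ids:
        raise KeyError(f"unknown sample '{sample}'")
    j = sample_ids.index(sample)
    rows, cols = model.config.rows, model.config.cols
    values, occupied = _unit_values(model, matrix)
    grid = fill_empty_units(values[:, j].reshape(rows, cols), occupied.reshape(rows, cols))
    return Portrait(grid=grid, subject=sample, kind="individual")


def mean_portrait(portraits: Sequence[Portrait], subject: str = "mean") -> Portrait:
    if not portraits:
        raise ValueError("need at least one portrait")
    shape = portraits[0].grid.shape
    for p in portraits:
        if p.grid.shape != shape:
            raise ValueError("portrait grid shapes differ")
    grid = np.mean([p.grid for p in portraits], axis=0)
    return Portrait(grid=grid, subject=subject, kind="mean")


def difference_portrait(a: Portrait, b: Portrait) -> Portrait:
    if a.grid.shape != b.grid.shape:
        raise ValueError("portrait grid shapes differ")
    return Portrait(grid=a.grid - b.grid, subject=f"{a.subject}-{b.subject}", kind="difference")


@dataclasses.dataclass
class ColorMap:
    """Ternary score coloring: blue (major), green (het), red (minor) bands.

    Cut points default to equal thirds of the [0, 2] score range; intensity
    scales within each band.
    """

    low_cut: float = 2.0 / 3.0
    high_cut: float = 4.0 / 3.0

    def __post_init__(self) -> None:
        if not 0.0 < self.low_cut < self.high_cut < 2.0:
            raise ValueError("cut points must be strictly increasing inside (0, 2)")

    def rgb(self, grid: np.ndarray) -> np.ndarray:
        """Map a [0, 2] score grid to uint8 RGB."""
        g = np.clip(np.asarray(grid, dtype=float), 0.0, 2.0)
        out = np.zeros(g.shape + (3,), dtype=np.uint8)
        blue = g < self.low_cut
        green = (g >= self.low_cut) & (g < self.high_cut)
        red = g >= self.high_cut
        # blue band: deep blue at 0 fading toward cyan-ish light blue
        t = np.where(blue, g / self.low_cut, 0.0)
        out[..., 2][blue] = 255
        out[..., 1][blue] = (180 * t[blue]).astype(np.uint8)
        # green band: full green, brightness peaking mid-band
        t = np.where(green, (g - self.low_cut) / (self.high_cut - self.low_cut), 0.0)
        out[..., 1][green] = (155 + 100 * (1 - np.abs(2 * t[green] - 1))).astype(np.uint8)
        # red band: light red deepening to saturated red at 2
        t = np.where(red, (g - self.high_cut) / (2.0 - self.high_cut), 0.0)
        out[..., 0][red] = 255
        out[..., 1][red] = (120 * (1 - t[red])).astype(np.uint8)
        return out

    def rgb_diverging(self, grid: np.ndarray) -> np.ndarray:
        """Symmetric diverging map for difference portraits on [-2, 2]."""
        g = np.clip(np.asarray(grid, dtype=float), -2.0, 2.0) / 2.0
        out = np.full(g.shape + (3,), 255, dtype=np.uint8)
        neg = g < 0
        pos = g > 0
        out[..., 0][neg] = (255 * (1 + g[neg])).astype(np.uint8)
        out[..., 1][neg] = (255 * (1 + g[neg])).astype(np.uint8)
        out[..., 1][pos] = (255 * (1 - g[pos])).astype(np.uint8)
        out[..., 2][pos] = (255 * (1 - g[pos])).astype(np.uint8)
        return out


def render(
    portrait: Portrait,
    path: str | os.PathLike,
    colormap: ColorMap | None = None,
    scale: int = 8,
) -> None:
    """Write a PNG of the portrait; a pure function of (grid, colormap)."""
    colormap = colormap or ColorMap()
    if portrait.kind == "difference":
        rgb = colormap.rgb_diverging(portrait.grid)
    else:
        rgb = colormap.rgb(portrait.grid)
    rgb = np.kron(rgb, np.ones((scale, scale, 1), dtype=np.uint8))
    Image.fromarray(rgb, mode="RGB").save(path, format="PNG")
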