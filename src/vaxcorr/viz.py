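"""Pixel-map rendering of correlation matrices.

Rendering conventions:

* matrices are drawn **rotated**: the bottom row of the conventional matrix
  becomes the top row of the image (columns are unchanged), so the main
  diagonal runs from bottom-left to top-right;
* **tricolor** mode colors each entry by threshold: red for rho > t, white
  for |rho| <= t, blue for rho < -t (default t = 0.01); undefined entries
  render white;
* **binned** mode maps entries to ``n_bins`` equal-width bins over [-1, 1]
  (default 20) on a green-centered diverging ramp: green near 0, shading to
  red toward +1 and to blue toward -1.  With an even bin count "around 0"
  spans the two central bins;
* when a block size is given, thin solid grid lines separate the vaccine
  blocks, and bold dashed lines mark vaccine-class boundaries.

Rendering is a pure function of the matrix and the spec: the same input
yields byte-identical PNG files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
import numpy as np
from PIL import Image

from .corrmat import CorrelationMatrix
from .patterns import classify_matrix

__all__ = [
    "RenderSpec",
    "rotate_for_display",
    "bin_index",
    "tricolor_rgb",
    "binned_rgb",
    "render_tricolor",
    "render_binned",
]

_RED = np.array([255, 0, 0], dtype=np.uint8)
_BLUE = np.array([0, 0, 255], dtype=np.uint8)
_WHITE = np.array([255, 255, 255], dtype=np.uint8)
_GREEN = np.array([0, 160, 0], dtype=np.float64)
_BLACK = np.array([0, 0, 0], dtype=np.uint8)


@dataclass
class RenderSpec:
    """How to draw a correlation matrix."""

    mode: str = "tricolor"
    threshold: float = 0.01
    n_bins: int = 20
    block_size: int | None = None
    class_boundaries: tuple[int, ...] = field(default_factory=tuple)
    rotated: bool = True
    scale: int = 1

    def __post_init__(self) -> None:
        if self.mode not in {"tricolor", "binned"}:
            raise ValueError("mode must be 'tricolor' or 'binned'")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.n_bins < 3:
            raise ValueError("need at least 3 bins")
        if self.scale < 1:
            raise ValueError("scale must be a positive integer")

    def validate_against(self, n: int) -> None:
        if self.block_size is not None and n % self.block_size != 0:
            raise ValueError(f"block_size {self.block_size} does not divide matrix dim {n}")


def rotate_for_display(matrix: np.ndarray) -> np.ndarray:
    """Reverse the row order (columns unchanged).  Applying twice is the identity."""
    matrix = np.asarray(matrix)
    if matrix.ndim < 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("expected a square matrix")
    return matrix[::-1].copy()


def bin_index(value: float, n_bins: int = 20) -> int:
    """Equal-width bin of ``value`` over [-1, 1], clamped to ``[0, n_bins)``.

    E.g. with 20 bins of width 0.1, the value 0.55 falls in bin 15.
    """
    b = int(np.floor((value + 1.0) * n_bins / 2.0))
    return min(max(b, 0), n_bins - 1)


def _bin_palette(n_bins: int) -> np.ndarray:
    """Green-centered diverging palette: one RGB row per bin."""
    centers = -1.0 + (np.arange(n_bins) + 0.5) * 2.0 / n_bins
    palette = np.empty((n_bins, 3), dtype=np.uint8)
    for b, c in enumerate(centers):
        end = _RED if c > 0 else _BLUE
        frac = abs(c) / abs(centers).max()  # extreme bins fully saturated
        palette[b] = np.round(_GREEN + frac * (end.astype(np.float64) - _GREEN)).astype(np.uint8)
    return palette


def tricolor_rgb(corr: CorrelationMatrix, t: float = 0.01) -> np.ndarray:
    """Per-cell RGB array (conventional orientation) for tricolor mode."""
    cats = classify_matrix(corr.values, corr.defined_mask, t=t)
    rgb = np.empty(cats.shape + (3,), dtype=np.uint8)
    rgb[:] = _WHITE
    rgb[cats == 1] = _RED
    rgb[cats == -1] = _BLUE
    return rgb


def binned_rgb(corr: CorrelationMatrix, n_bins: int = 20) -> np.ndarray:
    """Per-cell RGB array (conventional orientation) for binned mode."""
    palette = _bin_palette(n_bins)
    bins = np.floor((corr.values + 1.0) * n_bins / 2.0).astype(np.int64)
    np.clip(bins, 0, n_bins - 1, out=bins)
    rgb = palette[bins]
    rgb[~corr.defined_mask] = _WHITE
    return rgb


def _separator_positions(n: int, spec: RenderSpec) -> dict[int, str]:
    seps: dict[int, str] = {}
    if spec.block_size:
        for p in range(spec.block_size, n, spec.block_size):
            seps[p] = "solid"
    for p in spec.class_boundaries:
        if 0 < p < n:
            seps[p] = "dashed"
    return seps


def _sep_strip(length: int, kind: str, vertical: bool) -> np.ndarray:
    """A separator line: 1px solid black, or 2px bold dashed (4px dash period)."""
    width = 1 if kind == "solid" else 2
    strip = np.zeros((length, width, 3), dtype=np.uint8)
    if kind == "dashed":
        dash_off = (np.arange(length) // 4) % 2 == 1
        strip[dash_off] = _WHITE
    return strip if vertical else strip.transpose(1, 0, 2)


def _assemble(cells: np.ndarray, spec: RenderSpec) -> np.ndarray:
    """Upscale cell colors, insert grid lines, and apply display rotation."""
    n = cells.shape[0]
    spec.validate_against(n)
    img = np.repeat(np.repeat(cells, spec.scale, axis=0), spec.scale, axis=1)
    positions = _separator_positions(n, spec)
    if positions:
        # vertical separator columns first, then horizontal separator rows
        # (the row pass spans the already-widened image).
        for concat_axis in (1, 0):
            vertical = concat_axis == 1
            segments = []
            prev = 0
            for p in sorted(positions):
                if vertical:
                    segments.append(img[:, prev * spec.scale : p * spec.scale])
                else:
                    segments.append(img[prev * spec.scale : p * spec.scale, :])
                length = img.shape[0] if vertical else img.shape[1]
                segments.append(_sep_strip(length, positions[p], vertical))
                prev = p
            segments.append(
                img[:, prev * spec.scale :] if vertical else img[prev * spec.scale :, :]
            )
            img = np.concatenate(segments, axis=concat_axis)
    if spec.rotated:
        img = img[::-1]
    return np.ascontiguousarray(img)


def _write_png(img: np.ndarray, path: str | os.PathLike) -> None:
    Image.fromarray(img, mode="RGB").save(str(path), format="PNG")


def render_tricolor(
    corr: CorrelationMatrix, spec: RenderSpec, path: str | os.PathLike
) -> str:
    """Render ``corr`` as a red/white/blue threshold map PNG; returns the path."""
    if spec.mode != "tricolor":
        raise ValueError("spec.mode must be 'tricolor'")
    _write_png(_assemble(tricolor_rgb(corr, t=spec.threshold), spec), path)
    return str(path)


def render_binned(
    corr: CorrelationMatrix, spec: RenderSpec, path: str | os.PathLike
) -> str:
    """Render ``corr`` on the green-centered binned diverging palette; returns the path."""
    if spec.mode != "binned":
        raise ValueError("spec.mode must be 'binned'")
    _write_png(_assemble(binned_rgb(corr, n_bins=spec.n_bins), spec), path)
    return str(path)
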