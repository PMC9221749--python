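"""Equally spaced rectangular tiling of 2-D (or channel-stacked) arrays.

A tile count is mapped to a ``rows x cols`` grid whose tiles are as square
as possible, the image is partitioned into half-open pixel rectangles whose
per-axis sizes differ by at most one pixel, and per-tile arrays can be
stitched back into the full image bit-exactly.

Conventions: 0-based indices, half-open ``[start, end)`` intervals,
row-major tile order, row = first spatial axis.  Tiles never overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "GridLayout",
    "TileRegion",
    "select_grid",
    "tile_bounds",
    "extract_tiles",
    "stitch_tiles",
]

# Tie tolerance for aspect scores; |log a| vs |log 1/a| may differ in the
# last float bit, which must still count as a tie.
_TIE_EPS = 1e-9


@dataclass(frozen=True)
class GridLayout:
    """A factorization of a tile count into grid rows and columns."""

    n_tiles: int
    rows: int
    cols: int

    def __post_init__(self) -> None:
        if self.n_tiles < 1 or self.rows < 1 or self.cols < 1:
            raise ValueError("n_tiles, rows and cols must all be >= 1")
        if self.rows * self.cols != self.n_tiles:
            raise ValueError(
                f"rows*cols = {self.rows * self.cols} != n_tiles = {self.n_tiles}"
            )


@dataclass(frozen=True)
class TileRegion:
    """Half-open pixel rectangle [row_start, row_end) x [col_start, col_end)."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.row_start < self.row_end):
            raise ValueError(f"invalid row interval [{self.row_start}, {self.row_end})")
        if not (0 <= self.col_start < self.col_end):
            raise ValueError(f"invalid col interval [{self.col_start}, {self.col_end})")

    @property
    def height(self) -> int:
        return self.row_end - self.row_start

    @property
    def width(self) -> int:
        return self.col_end - self.col_start

    @property
    def area(self) -> int:
        return self.height * self.width

    def to_dict(self) -> dict:
        """JSON-serializable form for audit logs."""
        return asdict(self)


def select_grid(n_tiles: int, height: int, width: int) -> GridLayout:
    """Choose the rows x cols factorization of ``n_tiles`` giving the most
    square tiles for an image of the given extent.

    The score of a factor pair ``(r, c)`` is ``|log((width/c) / (height/r))|``
    (absolute log tile aspect ratio); ties are broken toward more columns,
    which suits wider-than-tall images.
    """
    if n_tiles < 1:
        raise ValueError(f"n_tiles must be >= 1, got {n_tiles}")
    if height < 1 or width < 1:
        raise ValueError("image extent must be positive")
    if height < n_tiles and width < n_tiles:
        # no factorization can give every tile >= 1 px on both axes
        raise ValueError(
            f"image {height}x{width} too small to split into {n_tiles} tiles"
        )

    best: tuple[float, int] | None = None
    best_pair: tuple[int, int] | None = None
    for rows in range(1, n_tiles + 1):
        if n_tiles % rows:
            continue
        cols = n_tiles // rows
        if rows > height or cols > width:
            continue
        score = abs(math.log((width / cols) / (height / rows)))
        if best is None or score < best[0] - _TIE_EPS or (
            abs(score - best[0]) <= _TIE_EPS and cols > best[1]
        ):
            best = (score, cols)
            best_pair = (rows, cols)
    if best_pair is None:
        raise ValueError(
            f"no factorization of {n_tiles} fits inside a {height}x{width} image"
        )
    return GridLayout(n_tiles=n_tiles, rows=best_pair[0], cols=best_pair[1])


def tile_bounds(layout: GridLayout, height: int, width: int) -> list[TileRegion]:
    """Partition a ``height x width`` image into the layout's regions.

    Boundary ``i`` along an axis of extent ``L`` split into ``k`` parts sits
    at ``floor(i*L/k)``, so sizes differ by at most one pixel and the regions
    tile the image exactly.  Regions are returned in row-major order.
    """
    if height < layout.rows or width < layout.cols:
        raise ValueError(
            f"grid {layout.rows}x{layout.cols} needs at least one pixel per tile "
            f"on each axis; image is {height}x{width}"
        )
    row_edges = [i * height // layout.rows for i in range(layout.rows + 1)]
    col_edges = [j * width // layout.cols for j in range(layout.cols + 1)]
    return [
        TileRegion(row_edges[i], row_edges[i + 1], col_edges[j], col_edges[j + 1])
        for i in range(layout.rows)
        for j in range(layout.cols)
    ]


def _check_spatial(array: np.ndarray) -> tuple[int, int]:
    if array.ndim < 2:
        raise ValueError("array must have at least 2 dimensions (H, W last)")
    return array.shape[-2], array.shape[-1]


def extract_tiles(array: np.ndarray, regions: Sequence[TileRegion]) -> list[np.ndarray]:
    """Cut exact sub-arrays (no interpolation, no padding) for each region.

    The last two axes are spatial; leading axes (e.g. mask channels) are kept.
    """
    height, width = _check_spatial(array)
    crops = []
    for region in regions:
        if region.row_end > height or region.col_end > width:
            raise ValueError(f"region {region} outside {height}x{width} array")
        crops.append(
            array[..., region.row_start : region.row_end, region.col_start : region.col_end].copy()
        )
    return crops


def stitch_tiles(
    crops: Sequence[np.ndarray],
    regions: Sequence[TileRegion],
    height: int,
    width: int,
) -> np.ndarray:
    """Reassemble per-region crops into the full array.

    Every output pixel must be written exactly once; overlapping or missing
    regions raise.
    """
    if len(crops) != len(regions):
        raise ValueError(f"{len(crops)} crops for {len(regions)} regions")
    if not crops:
        raise ValueError("nothing to stitch")

    lead = crops[0].shape[:-2]
    out = np.empty(lead + (height, width), dtype=crops[0].dtype)
    writes = np.zeros((height, width), dtype=np.uint8)
    for crop, region in zip(crops, regions):
        if crop.shape[:-2] != lead:
            raise ValueError("crops disagree on leading (channel) axes")
        if crop.shape[-2:] != (region.height, region.width):
            raise ValueError(
                f"crop shape {crop.shape[-2:]} does not match region "
                f"{(region.height, region.width)}"
            )
        if region.row_end > height or region.col_end > width:
            raise ValueError(f"region {region} outside {height}x{width} output")
        out[..., region.row_start : region.row_end, region.col_start : region.col_end] = crop
        writes[region.row_start : region.row_end, region.col_start : region.col_end] += 1
    if not (writes == 1).all():
        raise ValueError("regions do not partition the output (gap or overlap)")
    return out
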