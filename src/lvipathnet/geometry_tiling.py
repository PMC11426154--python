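"""Coordinate arithmetic and whole-slide tiling.

Two tiling strategies feed the segmenter, mirroring how gigapixel slides
are sliced in practice:

* **mask-grid tiling** — a fixed grid (default 2048- and 4096-px cells)
  anchored at the plane origin; every cell that intersects a vessel's mask
  is emitted, so an elongated vessel yields several cells;
* **bbox tiling** — one square tile centered on the vessel mask's centroid.

Also here: micron/pixel conversion, reflection padding of training tiles,
the deterministic dataset splitter, and mean-stitching of overlapping tile
predictions back onto a plane.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np

from ._rng import substream
from .types import AnnotationPolygon, SlidePlane, SplitPlan, TileSpec

__all__ = [
    "um_to_px",
    "mask_grid_tiles",
    "bbox_tile",
    "reflect_pad",
    "crop_padded",
    "split_dataset",
    "split_sizes",
    "grid_tiles",
    "stitch",
]

log = logging.getLogger(__name__)

DEFAULT_CELL_SIZES = (2048, 4096)


def um_to_px(length_um: float, mpp: float) -> int:
    """Convert a physical length to pixels, round-half-up, minimum 1.

    A 128 um classifier tile at 0.5 um/px becomes 256 px.
    """
    if not length_um > 0 or not mpp > 0:
        raise ValueError("length_um and mpp must be positive")
    return max(1, int(math.floor(length_um / mpp + 0.5)))


def mask_grid_tiles(
    plane: SlidePlane,
    polygons: Iterable[AnnotationPolygon],
    cell_sizes: Sequence[int] = DEFAULT_CELL_SIZES,
) -> list[TileSpec]:
    """Grid cells (anchored at the plane origin) intersecting each polygon.

    For each polygon and each cell size, emits the non-overlapping grid
    cells whose pixel footprint intersects the polygon's rasterized mask,
    clamped to the plane bounds. Identical specs are deduplicated. Empty
    (degenerate) polygons are skipped with a warning.
    """
    if not cell_sizes:
        raise ValueError("cell_sizes must be non-empty")
    H, W = plane.shape
    seen: set[TileSpec] = set()
    out: list[TileSpec] = []
    for poly in polygons:
        mask = poly.rasterize((H, W))
        ys, xs = np.nonzero(mask)
        if len(ys) == 0:
            log.warning("skipping empty polygon (label=%s)", poly.label)
            continue
        for cell in cell_sizes:
            if cell < 1:
                raise ValueError("cell sizes must be >= 1")
            cells = set(zip((xs // cell).tolist(), (ys // cell).tolist()))
            for cx, cy in sorted(cells):
                x0, y0 = cx * cell, cy * cell
                w = min(cell, W - x0)
                h = min(cell, H - y0)
                spec = TileSpec(x0, y0, w, h, source=plane.name)
                if spec not in seen:
                    seen.add(spec)
                    out.append(spec)
    return out


def mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    """First-moment centroid (x, y) of a binary mask."""
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        raise ValueError("empty mask has no centroid")
    return float(xs.mean()), float(ys.mean())


def bbox_tile(
    polygon: AnnotationPolygon | np.ndarray,
    out_size: int,
    plane: SlidePlane,
) -> TileSpec:
    """Square tile of side ``out_size`` centered on the polygon's centroid.

    The tile is translated (never shrunk) to stay inside the plane; the
    centroid always remains inside the tile. Vessels larger than
    ``out_size`` belong to :func:`mask_grid_tiles` instead.
    """
    H, W = plane.shape
    if out_size > W or out_size > H:
        raise ValueError(f"out_size {out_size} exceeds plane {W}x{H}")
    mask = (
        polygon.rasterize((H, W))
        if isinstance(polygon, AnnotationPolygon)
        else np.asarray(polygon, dtype=bool)
    )
    cx, cy = mask_centroid(mask)
    x = int(math.floor(cx + 0.5)) - out_size // 2
    y = int(math.floor(cy + 0.5)) - out_size // 2
    x = min(max(x, 0), W - out_size)
    y = min(max(y, 0), H - out_size)
    return TileSpec(x, y, out_size, out_size, source=plane.name)


def reflect_pad(tile_image: np.ndarray, style: str = "reflect") -> np.ndarray:
    """Double a tile by mirroring it right and down: H x W -> 2H x 2W.

    The original occupies the top-left block; the right, bottom and
    diagonal blocks continue the image by reflection so a vessel cut by
    the tile edge regains plausible context. ``style`` is numpy's pad
    mode: ``"reflect"`` (default; the shared boundary row/column is not
    duplicated) or ``"symmetric"`` (exact mirror blocks).
    """
    img = np.asarray(tile_image)
    if img.ndim < 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("tile must be a non-empty 2D image")
    if style not in ("reflect", "symmetric"):
        raise ValueError("style must be 'reflect' or 'symmetric'")
    H, W = img.shape[:2]
    pad = [(0, H), (0, W)] + [(0, 0)] * (img.ndim - 2)
    return np.pad(img, pad, mode=style)


def crop_padded(padded: np.ndarray) -> np.ndarray:
    """Inverse of :func:`reflect_pad`: recover the original top-left block."""
    H2, W2 = padded.shape[:2]
    if H2 % 2 or W2 % 2:
        raise ValueError("padded image must have even dimensions")
    return padded[: H2 // 2, : W2 // 2]


def split_sizes(n_items: int, plan: SplitPlan) -> dict[str, int]:
    """Partition sizes: floor quotas plus leftovers cycled by priority.

    Floor rounding followed by priority assignment reproduces both common
    conventions: 14,624 items at 70/15/15 with leftover->train gives
    (10238, 2193, 2193); 1,522 at 80/15/5 with leftover->test gives
    (1217, 228, 77).
    """
    names = [n for n, _ in plan.fractions]
    if n_items < len(names):
        raise ValueError("need at least one item per partition")
    sizes = {n: int(math.floor(f * n_items)) for n, f in plan.fractions}
    leftover = n_items - sum(sizes.values())
    i = 0
    while leftover > 0:
        sizes[plan.leftover_priority[i % len(plan.leftover_priority)]] += 1
        leftover -= 1
        i += 1
    return sizes


def split_dataset(n_items: int, plan: SplitPlan) -> dict[str, np.ndarray]:
    """Assign item indices 0..n-1 to partitions by a seeded shuffle.

    Sizes are deterministic given (n_items, plan); only membership varies
    with the seed. Returns name -> sorted index array.
    """
    sizes = split_sizes(n_items, plan)
    rng = substream(plan.seed, "split")
    order = rng.permutation(n_items)
    out: dict[str, np.ndarray] = {}
    start = 0
    for name, _ in plan.fractions:
        out[name] = np.sort(order[start : start + sizes[name]])
        start += sizes[name]
    return out


def grid_tiles(
    plane_shape: tuple[int, int],
    tile_size: int,
    overlap: float = 0.0,
    source: str = "plane",
) -> list[TileSpec]:
    """Regular inference grid with fractional ``overlap`` between tiles.

    Tiles are clamped to the plane; a tile larger than the plane collapses
    to one plane-sized tile. The grid always reaches the far edges.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    H, W = plane_shape
    th, tw = min(tile_size, H), min(tile_size, W)
    stride_y = max(1, int(round(th * (1 - overlap))))
    stride_x = max(1, int(round(tw * (1 - overlap))))
    ys = list(range(0, max(H - th, 0) + 1, stride_y))
    xs = list(range(0, max(W - tw, 0) + 1, stride_x))
    if ys[-1] != H - th:
        ys.append(H - th)
    if xs[-1] != W - tw:
        xs.append(W - tw)
    return [TileSpec(x, y, tw, th, source=source) for y in ys for x in xs]


def stitch(
    tile_probs: Sequence[tuple[TileSpec, np.ndarray]],
    plane_shape: tuple[int, int],
    overlap_policy: str = "mean",
) -> np.ndarray:
    """Accumulate tile probability maps onto a plane-sized map.

    Each pixel gets the arithmetic mean of all covering tiles' values;
    uncovered pixels are 0. The caller must crop away any reflection
    padding before stitching.
    """
    if overlap_policy != "mean":
        raise ValueError("only the 'mean' overlap policy is supported")
    H, W = plane_shape
    acc = np.zeros((H, W), dtype=np.float64)
    cnt = np.zeros((H, W), dtype=np.int64)
    for spec, prob in tile_probs:
        prob = np.asarray(prob)
        if prob.shape != (spec.h, spec.w):
            raise ValueError(f"prob map {prob.shape} does not match {spec}")
        if spec.y + spec.h > H or spec.x + spec.w > W:
            raise ValueError(f"{spec} exceeds plane {plane_shape}")
        acc[spec.y : spec.y + spec.h, spec.x : spec.x + spec.w] += prob
        cnt[spec.y : spec.y + spec.h, spec.x : spec.x + spec.w] += 1
    np.divide(acc, cnt, out=acc, where=cnt > 0)
    return acc
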