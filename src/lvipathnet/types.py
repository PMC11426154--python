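"""Core domain types shared across the pipeline.

Coordinate conventions: pixel coordinates are 0-based with the origin at the
top-left of a slide plane; rectangles are half-open ``[x, x+w) x [y, y+h)``.
Physical scale is carried as microns-per-pixel (``mpp``), roughly 0.5 at
x20 scanner magnification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SlidePlane",
    "AnnotationPolygon",
    "TileSpec",
    "SplitPlan",
    "VESSEL_KINDS",
    "INVASION_STATES",
]

#: Vessel caliber classes with their diameter ranges in microns.
VESSEL_KINDS: dict[str, tuple[float, float]] = {
    "artery": (100.0, 500.0),
    "vein": (100.0, 200.0),
    "capillary": (10.0, 50.0),
    "lymphatic": (20.0, 30.0),
}

#: Annotation states: clean, tumor embolus in the lumen (pooled with
#: epithelial displacement), or tumor cells within the wall only.
INVASION_STATES = ("clean", "luminal_invasion", "intramural_invasion")


@dataclass
class SlidePlane:
    """A 2D RGB image grid plus its physical scale.

    Attributes
    ----------
    pixels : (H, W, 3) uint8 array
    mpp : microns per pixel, > 0
    name : identifier used by TileSpec.source
    """

    pixels: np.ndarray
    mpp: float
    name: str = "plane"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("SlidePlane.pixels must be H x W x 3")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("SlidePlane must have H, W >= 1")
        if not self.mpp > 0:
            raise ValueError("mpp must be positive")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return self.height, self.width


@dataclass
class AnnotationPolygon:
    """A closed polygon in level-0 pixel coordinates with a state label.

    ``vertices`` is an (N, 2) float array of (x, y) pairs; the ring is
    implicitly closed (first vertex not repeated).
    """

    vertices: np.ndarray
    label: str
    kind: str | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array of (x, y)")
        if len(self.vertices) >= 2 and np.allclose(self.vertices[0], self.vertices[-1]):
            self.vertices = self.vertices[:-1]
        if self.label not in INVASION_STATES:
            raise ValueError(f"unknown label {self.label!r}")

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        """Binary mask of the polygon interior on an H x W grid."""
        from skimage.draw import polygon as _sk_polygon

        mask = np.zeros(shape, dtype=bool)
        if len(self.vertices) < 3:
            return mask
        rr, cc = _sk_polygon(self.vertices[:, 1], self.vertices[:, 0], shape=shape)
        mask[rr, cc] = True
        return mask


@dataclass(frozen=True)
class TileSpec:
    """Half-open pixel rectangle ``[x, x+w) x [y, y+h)`` on a named plane."""

    x: int
    y: int
    w: int
    h: int
    source: str = "plane"

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise ValueError("tile extent must be >= 1 px")
        if self.x < 0 or self.y < 0:
            raise ValueError("tile origin must be non-negative")

    def crop(self, image: np.ndarray) -> np.ndarray:
        if self.y + self.h > image.shape[0] or self.x + self.w > image.shape[1]:
            raise ValueError(f"{self} exceeds image of shape {image.shape[:2]}")
        return image[self.y : self.y + self.h, self.x : self.x + self.w]


@dataclass
class SplitPlan:
    """Deterministic partitioning recipe: named fractions plus a leftover rule.

    ``fractions`` is an ordered sequence of (name, fraction) summing to 1;
    leftover items (from floor rounding) are assigned one-by-one cycling
    through ``leftover_priority``.
    """

    fractions: Sequence[tuple[str, float]]
    leftover_priority: Sequence[str]
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.fractions)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")
        names = {n for n, _ in self.fractions}
        if not set(self.leftover_priority) <= names:
            raise ValueError("leftover_priority names must be partition names")
        if not self.leftover_priority:
            raise ValueError("leftover_priority must not be empty")
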