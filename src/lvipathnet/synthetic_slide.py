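"""Seeded synthetic H&E-like slides with ground-truth vessel annotations.

Real training data for this pipeline are gigapixel scans of lung
adenocarcinoma sections with expert-annotated vessels; those cannot be
redistributed. This module generates small stand-in planes that preserve
exactly the properties the pipeline depends on, so every downstream stage
is trainable and testable offline:

* four vessel caliber classes with their physical diameter ranges
  (arteries 100-500 um, veins 100-200 um, capillaries 10-50 um,
  lymphatics 20-30 um), rendered as rotated elliptical rings — an
  eosin-pink wall around a pale lumen — on an alveolar-like background;
* three states per vessel: clean, luminal invasion (a hematoxylin-dark
  embolus whose shape matches the lumen), and intramural invasion (dark
  cell nests inside the wall ring only, lumen free);
* annotation hygiene rules: polygons cover wall plus lumen (all tunicae),
  never overlap each other, and never touch the plane border;
* controllable stain drift and noise, giving the stain normalizer
  something to correct.

Appearance is deliberately flat-shaded, not photorealistic: the point is
to exercise the pipeline, not to fool a pathologist.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.color import lab2rgb, rgb2lab

from ._rng import substream
from .types import INVASION_STATES, VESSEL_KINDS, AnnotationPolygon, SlidePlane

__all__ = [
    "SceneConfig",
    "SyntheticSlide",
    "VesselSprite",
    "PlacementError",
    "render_vessel",
    "generate_scene",
    "export_annotations",
    "read_annotations",
    "save_slide",
]

# Wall thickness as a fraction of the semi-minor radius, by caliber class.
# Arteries carry a prominent muscular media; lymphatics are endothelium-thin.
_WALL_FRACTION = {"artery": 0.35, "vein": 0.18, "capillary": 0.28, "lymphatic": 0.15}

_WALL_RGB = np.array([226, 130, 170], dtype=float)      # eosin pink
_LUMEN_RGB = np.array([244, 238, 244], dtype=float)     # pale lumen
_TUMOR_RGB = np.array([92, 58, 128], dtype=float)       # hematoxylin-dark cells
_BG_RGB = np.array([241, 233, 238], dtype=float)        # airspace
_SEPTA_RGB = np.array([222, 178, 198], dtype=float)     # alveolar septa


class PlacementError(RuntimeError):
    """Raised when a vessel cannot be placed within the retry budget."""


@dataclass
class SceneConfig:
    """Recipe for one synthetic slide.

    ``n_vessels_by_kind`` maps caliber class to count;
    ``invasion_fraction`` is the fraction of vessels carrying invasion, of
    which ``intramural_fraction`` are intramural (the rest luminal);
    ``stain_jitter`` in [0, 1] scales a global stain shift of the
    rendered plane.
    """

    # default field: ~1 mm^2 at 2 um/px, room for one full-size artery
    width_px: int = 512
    height_px: int = 512
    mpp: float = 2.0
    n_vessels_by_kind: dict[str, int] = field(
        default_factory=lambda: {"artery": 1, "vein": 1, "capillary": 3, "lymphatic": 2}
    )
    invasion_fraction: float = 0.0
    intramural_fraction: float = 0.0
    stain_jitter: float = 0.0
    seed: int = 0
    retry_budget: int = 200

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("plane dimensions must be positive")
        if not self.mpp > 0:
            raise ValueError("mpp must be positive")
        for kind, count in self.n_vessels_by_kind.items():
            if kind not in VESSEL_KINDS:
                raise ValueError(f"unknown vessel kind {kind!r}")
            if count < 0:
                raise ValueError("vessel counts must be >= 0")
        for name in ("invasion_fraction", "intramural_fraction", "stain_jitter"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class VesselSprite:
    """One rendered vessel on its local canvas.

    ``mask`` covers wall plus lumen (all tunicae) and equals the
    rasterization of ``polygon_xy`` (local coordinates); ``tumor_mask``
    holds embolus or intramural-nest pixels, empty for clean vessels.
    """

    image: np.ndarray
    mask: np.ndarray
    polygon_xy: np.ndarray
    lumen_mask: np.ndarray
    wall_mask: np.ndarray
    tumor_mask: np.ndarray
    kind: str
    state: str
    diameter_um: float


@dataclass
class PlacedVessel:
    polygon: AnnotationPolygon
    state: str
    kind: str
    offset_xy: tuple[int, int]
    tumor_mask_global: np.ndarray  # (n, 2) array of (y, x) tumor pixels


@dataclass
class SyntheticSlide:
    """A rendered plane plus its exact ground truth."""

    plane: SlidePlane
    truth_polygons: list[AnnotationPolygon]
    truth_mask: np.ndarray
    provenance: SceneConfig
    vessels: list[PlacedVessel] = field(default_factory=list)


def _ellipse_polygon(cx: float, cy: float, a: float, b: float, theta: float,
                     n_points: int = 64) -> np.ndarray:
    """(N, 2) array of (x, y) vertices of a rotated ellipse."""
    t = np.linspace(0.0, 2.0 * math.pi, n_points, endpoint=False)
    ct, st = math.cos(theta), math.sin(theta)
    x = cx + a * np.cos(t) * ct - b * np.sin(t) * st
    y = cy + a * np.cos(t) * st + b * np.sin(t) * ct
    return np.column_stack([x, y])


def _rasterize_xy(poly_xy: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    from skimage.draw import polygon as _sk_polygon

    mask = np.zeros(shape, dtype=bool)
    rr, cc = _sk_polygon(poly_xy[:, 1], poly_xy[:, 0], shape=shape)
    mask[rr, cc] = True
    return mask


def render_vessel(kind: str, diameter_um: float, state: str, mpp: float,
                  seed: int | np.random.Generator = 0) -> VesselSprite:
    """Render one vessel sprite on a local canvas.

    The outer (annotated) ellipse has major diameter ``diameter_um/mpp``
    pixels, eccentricity at most 0.8 and random orientation. Luminal
    invasion places an embolus that is a shrunk copy of the lumen ellipse
    (shape matched, strictly inside the lumen, disjoint from the wall);
    intramural invasion scatters dark nests inside the wall ring only.
    """
    if kind not in VESSEL_KINDS:
        raise ValueError(f"unknown vessel kind {kind!r}")
    if state not in INVASION_STATES:
        raise ValueError(f"unknown state {state!r}")
    lo, hi = VESSEL_KINDS[kind]
    if not lo <= diameter_um <= hi:
        raise ValueError(f"{kind} diameter must lie in [{lo}, {hi}] um")
    d_px = diameter_um / mpp
    if d_px < 2.0:
        raise ValueError(f"{diameter_um} um at {mpp} um/px is below 2 px — unrenderable")
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "render")

    a = d_px / 2.0
    ecc = rng.uniform(0.0, 0.8)
    b = a * math.sqrt(1.0 - ecc**2)
    theta = rng.uniform(0.0, math.pi)
    margin = 3
    side = int(math.ceil(2 * a)) + 2 * margin
    cx = cy = side / 2.0

    poly = _ellipse_polygon(cx, cy, a, b, theta)
    mask = _rasterize_xy(poly, (side, side))
    wall_frac = _WALL_FRACTION[kind]
    la, lb = max(a * (1 - wall_frac), 0.5), max(b * (1 - wall_frac), 0.5)
    lumen = _rasterize_xy(_ellipse_polygon(cx, cy, la, lb, theta), (side, side)) & mask
    wall = mask & ~lumen

    noise = rng.normal(0.0, 3.0, size=(side, side, 3))
    image = np.zeros((side, side, 3), dtype=float)
    image[lumen] = _LUMEN_RGB
    image[wall] = _WALL_RGB

    tumor = np.zeros((side, side), dtype=bool)
    if state == "luminal_invasion":
        emb = _rasterize_xy(_ellipse_polygon(cx, cy, la * 0.7, lb * 0.7, theta),
                            (side, side))
        # keep the embolus strictly in the lumen, clear of the wall
        tumor = emb & lumen & ~ndi.binary_dilation(wall)
        if not tumor.any():
            tumor[int(round(cy)), int(round(cx))] = lumen[int(round(cy)), int(round(cx))]
        if not tumor.any():  # degenerate: claim the first lumen pixel
            ys, xs = np.nonzero(lumen)
            tumor[ys[0], xs[0]] = True
    elif state == "intramural_invasion":
        interior_wall = wall & ~ndi.binary_dilation(lumen)
        candidates = np.argwhere(interior_wall if interior_wall.any() else wall)
        n_nests = max(3, len(candidates) // 25)
        picks = candidates[rng.choice(len(candidates), size=min(n_nests, len(candidates)),
                                      replace=False)]
        for py, px in picks:
            yy, xx = np.ogrid[-1:2, -1:2]
            ys = np.clip(py + yy, 0, side - 1)
            xs = np.clip(px + xx, 0, side - 1)
            tumor[ys, xs] = True
        tumor &= wall & ~lumen
    image[tumor] = _TUMOR_RGB
    image = np.clip(image + noise, 0, 255)
    image[~mask] = 0

    return VesselSprite(image=image.astype(np.uint8), mask=mask, polygon_xy=poly,
                        lumen_mask=lumen, wall_mask=wall, tumor_mask=tumor,
                        kind=kind, state=state, diameter_um=diameter_um)


def _background(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Alveolar-like texture: pale airspace, thin septa, mild noise."""
    H, W = shape
    coarse = rng.normal(size=(max(H // 24, 2), max(W // 24, 2)))
    fieldmap = ndi.zoom(coarse, (H / coarse.shape[0], W / coarse.shape[1]), order=3)
    fieldmap = fieldmap[:H, :W]
    septa = np.abs(fieldmap) < 0.12
    img = np.tile(_BG_RGB, (H, W, 1))
    img[septa] = _SEPTA_RGB
    img += rng.normal(0.0, 4.0, size=img.shape)
    return np.clip(img, 0, 255)


def _assign_states(total: int, cfg: SceneConfig,
                   rng: np.random.Generator) -> list[str]:
    n_invaded = int(round(cfg.invasion_fraction * total))
    n_intra = int(round(cfg.intramural_fraction * n_invaded))
    states = ["clean"] * total
    invaded = rng.choice(total, size=n_invaded, replace=False) if n_invaded else []
    for i, idx in enumerate(invaded):
        states[idx] = "intramural_invasion" if i < n_intra else "luminal_invasion"
    return states


def _stain_shift(image: np.ndarray, jitter: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Global stain drift: shift/scale LAB channel statistics by severity."""
    lab = rgb2lab(image.astype(np.float64) / 255.0)
    shift = rng.normal(0.0, jitter * np.array([8.0, 6.0, 6.0]))
    scale = 1.0 + rng.normal(0.0, jitter * 0.15, size=3)
    for c in range(3):
        mu = lab[..., c].mean()
        lab[..., c] = (lab[..., c] - mu) * max(scale[c], 0.2) + mu + shift[c]
    return (np.clip(lab2rgb(lab), 0, 1) * 255.0 + 0.5).astype(np.uint8)


def generate_scene(config: SceneConfig) -> SyntheticSlide:
    """Generate a full synthetic slide from a :class:`SceneConfig`.

    Vessels are placed uniformly at random with at least a 2-px gap
    between masks and a 2-px clearance from the plane border (edge
    vessels are never placed, keeping the truth mask consistent with the
    polygon list). Placement failure after the retry budget raises
    :class:`PlacementError` naming the kind. Identical configs (including
    the seed) produce bit-identical slides.
    """
    cfg = config
    rng = substream(cfg.seed, "synth")
    H, W = cfg.height_px, cfg.width_px
    plane_img = _background((H, W), rng)
    occupancy = np.zeros((H, W), dtype=bool)
    truth_mask = np.zeros((H, W), dtype=bool)

    jobs: list[tuple[str, float]] = []
    for kind in sorted(cfg.n_vessels_by_kind):
        lo, hi = VESSEL_KINDS[kind]
        for _ in range(cfg.n_vessels_by_kind[kind]):
            jobs.append((kind, float(rng.uniform(lo, hi))))
    states = _assign_states(len(jobs), cfg, rng)
    # place large vessels first so they are not crowded out
    order = sorted(range(len(jobs)), key=lambda i: -jobs[i][1])

    polygons: list[AnnotationPolygon] = []
    vessels: list[PlacedVessel] = []
    border = 2
    for i in order:
        kind, diameter = jobs[i]
        sprite = render_vessel(kind, diameter, states[i], cfg.mpp, seed=rng)
        sh = sprite.mask.shape[0]
        if sh + 2 * border > min(H, W):
            raise PlacementError(
                f"a {kind} of {diameter:.0f} um does not fit a {W}x{H}px plane")
        grown = ndi.binary_dilation(sprite.mask, iterations=2)
        placed = False
        for _ in range(cfg.retry_budget):
            x0 = int(rng.integers(border, W - sh - border + 1))
            y0 = int(rng.integers(border, H - sh - border + 1))
            region = occupancy[y0 : y0 + sh, x0 : x0 + sh]
            if not (region & grown).any():
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place a {kind} after {cfg.retry_budget} tries")
        occupancy[y0 : y0 + sh, x0 : x0 + sh] |= grown
        truth_mask[y0 : y0 + sh, x0 : x0 + sh] |= sprite.mask
        target = plane_img[y0 : y0 + sh, x0 : x0 + sh]
        target[sprite.mask] = sprite.image[sprite.mask]
        poly = AnnotationPolygon(sprite.polygon_xy + np.array([x0, y0]),
                                 label=states[i], kind=kind)
        polygons.append(poly)
        tum = np.argwhere(sprite.tumor_mask) + np.array([y0, x0])
        vessels.append(PlacedVessel(polygon=poly, state=states[i], kind=kind,
                                    offset_xy=(x0, y0), tumor_mask_global=tum))

    plane_img = np.clip(plane_img, 0, 255).astype(np.uint8)
    if cfg.stain_jitter > 0:
        plane_img = _stain_shift(plane_img, cfg.stain_jitter, rng)
    plane = SlidePlane(plane_img, mpp=cfg.mpp, name=f"synthetic-{cfg.seed}")
    return SyntheticSlide(plane=plane, truth_polygons=polygons,
                          truth_mask=truth_mask, provenance=cfg, vessels=vessels)


# ---------------------------------------------------------------------------
# Annotation I/O (QuPath-dialect GeoJSON)
# ---------------------------------------------------------------------------


def export_annotations(slide: SyntheticSlide | list[AnnotationPolygon],
                       path: str | Path) -> None:
    """Write polygons as a GeoJSON FeatureCollection.

    Each Feature is a closed Polygon in level-0 pixel coordinates with
    the state under ``properties.classification.name`` — the dialect
    QuPath exports and re-imports.
    """
    polygons = slide if isinstance(slide, list) else slide.truth_polygons
    features = []
    for poly in polygons:
        ring = poly.vertices.tolist()
        ring.append(ring[0])  # writer closes the ring
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": {
                "object_type": "annotation",
                "classification": {"name": poly.label},
                **({"vessel_kind": poly.kind} if poly.kind else {}),
            },
        })
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload))


def read_annotations(path: str | Path) -> list[AnnotationPolygon]:
    """Read a QuPath-dialect GeoJSON back into polygons (exact round trip)."""
    payload = json.loads(Path(path).read_text())
    out = []
    for feat in payload.get("features", []):
        ring = np.asarray(feat["geometry"]["coordinates"][0], dtype=float)
        props = feat.get("properties", {})
        label = props.get("classification", {}).get("name", "clean")
        out.append(AnnotationPolygon(ring, label=label,
                                     kind=props.get("vessel_kind")))
    return out


def save_slide(slide: SyntheticSlide, out_dir: str | Path,
               image_format: str = "png") -> dict[str, Path]:
    """Write the plane image and its annotations to ``out_dir``.

    ``image_format``: "png" (small fixtures) or "tiff" (256-px tiled).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    name = slide.plane.name
    if image_format == "png":
        import imageio.v3 as iio

        img_path = out / f"{name}.png"
        iio.imwrite(img_path, slide.plane.pixels)
    elif image_format == "tiff":
        import tifffile

        img_path = out / f"{name}.tiff"
        tifffile.imwrite(img_path, slide.plane.pixels, tile=(256, 256))
    else:
        raise ValueError("image_format must be 'png' or 'tiff'")
    geo_path = out / f"{name}.geojson"
    export_annotations(slide, geo_path)
    meta_path = out / f"{name}.meta.json"
    meta_path.write_text(json.dumps({"mpp": slide.plane.mpp, "name": name}))
    return {"image": img_path, "annotations": geo_path, "meta": meta_path}
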