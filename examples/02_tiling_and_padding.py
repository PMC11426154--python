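"""Tiling arithmetic: micron conversion, the two tiling modes, reflection.

Shows how a vessel polygon maps to fixed-grid cells and to a centered
bounding-box tile, and how reflection padding doubles a training tile.
"""

import numpy as np

from lvipathnet import (
    SceneConfig, generate_scene, bbox_tile, mask_grid_tiles, reflect_pad,
    um_to_px,
)

print("128 um at 0.5 um/px ->", um_to_px(128, 0.5), "px")
print("128 um at 2.0 um/px ->", um_to_px(128, 2.0), "px")

slide = generate_scene(SceneConfig(
    width_px=288, height_px=288, mpp=2.0,
    n_vessels_by_kind={"vein": 1, "capillary": 2}, seed=3))

# fixed-grid tiling: every 96/192-px grid cell touching each vessel
tiles = mask_grid_tiles(slide.plane, slide.truth_polygons, cell_sizes=(96, 192))
print(f"mask-grid tiling emits {len(tiles)} cells for "
      f"{len(slide.truth_polygons)} vessels")

# bbox tiling: one square tile centered on the vessel's mask centroid
spec = bbox_tile(slide.truth_polygons[0], 64, slide.plane)
print(f"bbox tile for vessel 0: origin ({spec.x}, {spec.y}), {spec.w} px square")

crop = spec.crop(slide.plane.pixels)
padded = reflect_pad(crop)
print(f"reflection padding: {crop.shape[:2]} -> {padded.shape[:2]}, "
      f"top-left block identical: {np.array_equal(padded[:64, :64], crop)}")
# The padded tile gives a vessel cut by the tile edge mirrored context, so
# the segmenter sees a closed shape instead of a truncated one.
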