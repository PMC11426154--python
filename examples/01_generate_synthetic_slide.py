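"""Generate one synthetic H&E-like slide and export its ground truth.

Builds a 288x288-px plane at 2 um/px holding two veins, three capillaries
and two lymphatics, 40% of them carrying invasion, then writes the plane
as PNG plus a QuPath-dialect GeoJSON of the vessel polygons.
"""

from lvipathnet import SceneConfig, generate_scene, save_slide

config = SceneConfig(
    width_px=288, height_px=288, mpp=2.0,
    n_vessels_by_kind={"vein": 2, "capillary": 3, "lymphatic": 2},
    invasion_fraction=0.4, intramural_fraction=0.25,
    stain_jitter=0.15, seed=7,
)
slide = generate_scene(config)
paths = save_slide(slide, "example_output/slide")

print(f"plane: {slide.plane.width} x {slide.plane.height} px at {slide.plane.mpp} um/px")
print(f"vessels: {len(slide.truth_polygons)}, "
      f"vessel pixels: {int(slide.truth_mask.sum())}")
for vessel in slide.vessels:
    print(f"  {vessel.kind:10s} {vessel.state}")
print(f"wrote {paths['image']} and {paths['annotations']}")
# Each line above is one planted vessel with its invasion state; the GeoJSON
# polygons rasterize exactly to the returned truth mask.
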