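"""Segment a liver-ECM disc and split cells into on/off-disc sets.

Generates a synthetic well scan (textured 6 mm disc, vignetting, nuclear
spots), sweeps segmentation parameters, registers the cell centroids with
the winning mask, and builds the on-disc live-cell tally.
"""

import math

from ecmscreen import (
    DiscSceneParams,
    SegmentationParams,
    gen_well_scene,
    mask_iou,
    register_cells,
    sweep_segmentation,
)

scene = gen_well_scene(DiscSceneParams(seed=4))
grid = [SegmentationParams(std_kernel=k, struct_size=s) for k in (5, 7, 9) for s in (5, 7)]
expected_area = math.pi * 150.0**2  # 6 mm disc at 20 um/px
best, ranked = sweep_segmentation(scene.image, scene.profile, grid, expected_area)

print(f"swept {len(ranked)} parameter sets; winning score S = {best.score:.4f}")
print(f"mask area {best.area} px (expected {expected_area:.0f}), "
      f"circularity {best.circularity():.3f}")
print(f"IoU against ground truth: {mask_iou(best.mask, scene.mask):.3f}")

registered = register_cells(scene.cells.drop(columns=["on_disc"]), best)
n_on, n_off = int(registered["on_disc"].sum()), int((~registered["on_disc"]).sum())
agree = (registered["on_disc"] == scene.cells["on_disc"]).mean()
print(f"\nregistered {len(registered)} cells: {n_on} on-disc, {n_off} off-disc "
      f"({agree:.1%} agreement with truth)")
print("Only on-disc live cells enter the growth-rate fit; off-disc cells grow")
print("on bare plastic and would bias the scaffold growth estimate.")
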