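"""End-to-end pipeline on a synthetic immunohistochemistry image.

Generates a pseudo-IHC image (brown DAB blobs for stained cells, blue
hematoxylin nuclei, a pale bone band), detects and classifies cells via
colour deconvolution + watershed segmentation, fields the stained
population and allocates it to the paratrabecular niche by histogram
intersection with the bone field.
"""

import numpy as np

from histofield import (
    detect_cells,
    field_intersection,
    make_pseudo_ihc,
    niche_allocation,
    point_field,
)

img = make_pseudo_ihc(512, 512, n_stained=20, n_unstained=50, bone_bands=1, seed=7)
print(f"ground truth: {len(img.truth)} cells, {img.truth.stained.sum()} stained")

cells = detect_cells(img.pixels, max_dist=5)
print(f"detected:     {len(cells)} cells, {cells.stained.sum()} classified stained")

stained = cells.subset(cells.stained)
bone_field = point_field(img.bone_mask, img.bone_mask.shape)
cell_fields = [point_field([(r, c)], img.bone_mask.shape)
               for r, c in zip(stained.rows, stained.cols)]

alloc = niche_allocation(cell_fields, bone_field, intersection_threshold=0.5)
print(
    f"bone-niche intersection: {alloc.mean:0.2f} +- {alloc.sd:0.2f} "
    f"({int(alloc.allocated.sum())}/{len(cell_fields)} cells allocated at 0.5)"
)

pop_field = point_field(stained, img.bone_mask.shape)
print(f"stained-population field vs bone field: "
      f"intersection {field_intersection(pop_field, bone_field):0.2f}")
print(
    "\nPer-cell intersections quantify how paratrabecular the infiltrate\n"
    "is; a dense peritrabecular population scores high with a tight sd."
)
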