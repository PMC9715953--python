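"""Compute the 36-column feature table on a small phantom and show how
dichroism texture separates the two tissue regions.

Tumor-side sub-images have shorter spatial correlation of the SHG-CD field
(disordered fiber orientation), which raises GLCM contrast and entropy and
lowers IDM relative to the normal side — the contrast the clustering stage
exploits when intensity alone is uninformative.
"""

import dataclasses

import pshgmargin as pm
from pshgmargin.texture import build_feature_table, tile_grid

cfg = pm.PhantomConfig(
    image_height=512, image_width=512, tile_size=128, boundary_column=256, seed=3
)
truth = pm.generate_phantom(cfg)
stack = pm.synthesize_stack(truth, cfg)
cal = pm.fit_snr_calibration(
    pm.synthesize_stack(truth, dataclasses.replace(cfg, n_frames=8))
)
maps = pm.compute_parameter_maps(stack, calibration=cal)
grid = tile_grid(512, 512, 128)
table = build_feature_table(maps, grid)

print(f"{len(table)} retained sub-images, {len(table.columns) - 2} feature columns")
tumor = table[table.grid_col < 2]
normal = table[table.grid_col >= 2]
for col in ("pixel_density", "shg_mean", "shgcd_contrast", "shgcd_entropy", "shgcd_idm"):
    print(f"  {col:16s} tumor {tumor[col].mean():8.3f}   normal {normal[col].mean():8.3f}")
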