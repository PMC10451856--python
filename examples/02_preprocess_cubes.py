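"""Bounding box, global 16^3 cube and the 729-cube local augmentation.

Shows the preprocessing arithmetic on one in-memory phantom: the 2-voxel
expanded cubic bounding box, the resampled global cube, and the stride-2
sliding cut of the 32^3 region into 9 x 9 x 9 = 729 local cubes.
"""

from mvifusion.phantom import PhantomConfig, generate_study
from mvifusion.preprocess import augment_local_cubes, extract_global_cube, mask_to_bbox

study = generate_study(PhantomConfig(n_patients=1, volume_shape=(64, 64, 64), seed=7), 0, 1)
bbox = mask_to_bbox(study.mask)  # tumor + 2-voxel peritumoral margin, cubified
print(f"bounding box lo={bbox.lo} hi={bbox.hi} shape={bbox.shape}")

global_cube = extract_global_cube(study.volumes["HBP"], bbox)
print(f"global cube: {global_cube.data.shape} (kind={global_cube.kind})")

local = augment_local_cubes(study.volumes["HBP"], bbox)
offsets = sorted({c.offset[0] for c in local})
print(f"local cubes: {len(local)} at per-axis offsets {offsets}")
print("Each training tumor contributes 729 local + 1 global cube per phase;"
      " test patients contribute the global cube only.")
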