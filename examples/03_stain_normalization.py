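"""Tile a synthetic H&E image, drop background, and normalize its stains.

Draws one procedural slide image, cuts it into non-overlapping tiles,
excludes near-white tiles with the brightness-216 rule, fits a two-stain
optical-density model to the tissue tiles and re-expresses them through a
reference stain model.
"""

import numpy as np

from lactopath import histology, synthio

# one procedurally drawn "slide": a grid of generated tiles
bags = synthio.simulate_bags(
    synthio.BagSimConfig(n_slides=2, patches_per_slide=(4, 4), tile_edge=256,
                         seed=2),
    mode="images",
)
row = np.hstack([t.pixels for t in bags[0].tiles[:4]])
white = np.full((256, 256, 3), 250, dtype=np.uint8)
slide = np.hstack([row, white])  # append a background region

tiles = histology.tile_image(slide, slide_id="demo", tile_size=256)
flags = [histology.is_background(t, brightness_threshold=216) for t in tiles]
print(f"{len(tiles)} tiles, {sum(flags)} excluded as background")

tissue = [t for t, bg in zip(tiles, flags) if not bg]
source = histology.fit_stain_model(tissue, seed=0)
print("fitted stain matrix (columns: hematoxylin, eosin):")
print(source.stain_matrix.round(3))

# normalize to a canonical reference stain model
w_ref = np.array([[0.65, 0.07], [0.70, 0.99], [0.29, 0.11]])
w_ref /= np.linalg.norm(w_ref, axis=0)
target = histology.StainModel(stain_matrix=w_ref,
                              concentration_scale=source.concentration_scale)
normalized = [histology.normalize_tile(t, source, target) for t in tissue]
refit = histology.fit_stain_model(normalized, seed=0)
cos = [abs(refit.stain_matrix[:, i] @ w_ref[:, i]) for i in range(2)]
print(f"cosine similarity of re-estimated stains to the reference: "
      f"{cos[0]:.3f}, {cos[1]:.3f} (1.0 = exact)")
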