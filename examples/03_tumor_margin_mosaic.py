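"""Locate a tumor margin on a cell-density gradient mosaic.

Generates a 1x6 tile strip whose true cell density rises from
normal-brain levels (PoS 0.05) to tumor-core levels (PoS 0.30), then
classifies every tile.  The NORMAL -> TUMOR transition should fall on
the tile where the true density crosses the 0.17 threshold.
"""

from thgq import (ClassifierParams, PhantomSpec, PipelineConfig,
                  analyze_image, classify_mosaic, generate_gradient_mosaic)

spec = PhantomSpec(rng_seed=11)
tiles = generate_gradient_mosaic(spec, n_tiles=(1, 6),
                                 density_gradient=(0.05, 0.30))

cfg = PipelineConfig()
results, label_grid, _ = classify_mosaic(
    [img for img, _ in tiles],
    lambda im: analyze_image(im, cfg).features,
    ClassifierParams(quarter_large_tiles=False),
)

print("tile | true PoS | measured PoS | label")
for k, ((_, truth), res) in enumerate(zip(tiles, results)):
    print(f"  {k}  |   {truth.cell_pos:.3f}  |    {res.features.cell_pos:.3f}"
          f"     | {res.label.value}")
print("label grid:", label_grid.tolist())
# The margin (first TUMOR tile) should sit within one tile of the true
# 0.17 crossing; both density rules can fire near the margin.
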