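# thgq — cellularity quantification for label-free THG brain-tissue microscopy

Third harmonic generation (THG) microscopy images fresh, unstained brain
tissue at subcellular resolution: lipid-rich myelinated axons of the
neuropil appear as bright fibers, while cell bodies appear as dark
"holes", occasionally with a relatively bright nucleus visible inside.
Because diffuse gliomas infiltrate normal brain as a gradient of
increased cellularity, counting how much of an image is occupied by
cells is a direct, label-free readout of tumor infiltration — relevant
to neurosurgeons who need to judge, during resection, whether a tissue
margin is still infiltrated.

`thgq` implements the automated quantification workflow for such images:

1. **Preprocess** — histogram truncation + contrast-limited local
   histogram equalization, then salience-modulated Perona–Malik
   anisotropic diffusion (noise removed, edges kept sharp).
2. **Segment** — a three-phase piecewise-constant active-contour
   segmentation (threshold-dynamics minimization, phase means anchored
   to the intensity extremes) labels every pixel as *dark hole*,
   *bright object* or *background*; a modified circular Hough transform,
   in which each edge pixel votes only along its own gradient direction,
   rescues faint round/elliptical nuclei from the background.
3. **Classify objects** — dark components are hole-filled, split at
   necks (distance-transform watershed) and kept as brain cells when
   their area reaches 1000 px (≈6 µm × 6 µm at ~0.3 µm/px); bright
   components under 500 px are ignored, fiber-like ones
   (compactness 4πA/P² < 0.1) become neuropil, and compact ones
   (4πA/P² > 0.5, area < 10 000 px) become nuclei; cytoplasm and nuclei
   are merged into full brain-cell detections.
4. **Quantify & classify** — densities are summarized as *percentage of
   space* (PoS: union pixel count / image area) for cells and nuclei and
   as summed perimeter / 100 for neuropil; an image (or mosaic tile) is
   called **TUMOR** when cell PoS > 0.17 **or** nucleus PoS > 0.03
   (strict inequalities), otherwise **NORMAL**.  Tiles with a field of
   view of 500 µm and larger are split into four equal parts, each part
   classified, and the averaged quarter features represent the tile.

Because no public THG image sets exist, the package ships a first-class
phantom generator (`thgq.phantom`) that renders THG-like and paired
HOE-fluorescence-like scenes with pixel-exact ground truth, and every
stage is validated against those truths.

## Worked example

```python
from thgq import PhantomSpec, PipelineConfig, analyze_image, generate_phantom

spec = PhantomSpec(n_cells=30, rng_seed=7)          # ~300x300 um field
image, truth = generate_phantom(spec)
result = analyze_image(image, PipelineConfig())
```

Running `examples/02_quantify_single_image.py` (exactly the code above
plus printing) gives:

```
detected brain cells: 30 (planted: 30)
detected nuclei:      14
cell PoS:     0.063  (truth 0.059; tumor threshold 0.17)
nucleus PoS:  0.0107 (tumor threshold 0.03)
neuropil density (perimeter px / 100): 240.2
classification: NORMAL (rule fired: NONE)
```

All 30 planted cells are recovered; the measured cell PoS (0.063)
matches the ground-truth density (0.059) to within the PSF-blur margin,
and — being below both density thresholds — the image is called NORMAL.
The other scripts in `examples/` demonstrate phantom generation, tumor
margin localization on a density-gradient mosaic, THG-vs-HOE density
correlation with the leave-one-out exclusion analysis, and lossless
fixed-overlap mosaic stitching.

A thin command-line interface mirrors the library for batch use:
`thgq phantom`, `thgq preprocess`, `thgq segment`, `thgq classify`,
`thgq run`, `thgq stitch`, `thgq validate-hoe` (see `thgq --help`).

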