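# Methods

This note documents the models, parameter choices and numerical details
behind `thgq`, and what the phantom-based validation does and does not
establish.

## Imaging model and scale

The unit of analysis is a 2D grayscale intensity image of ~300 × 300 µm
sampled at ~1000 × 1000 px (0.3 µm/px).  All pixel thresholds are tied
to that scale: the 1000 px minimum cell area corresponds to ≈6 µm × 6 µm
of tissue.  Images are processed in [0, 1] after enhancement; all
coordinates are 0-based (row, col) with origin at the top-left.

## Preprocessing

**Enhancement.** Intensities are clipped at the (0.5, 99.5) percentiles
and rescaled, then locally equalized with CLAHE on an 8 × 8 tile grid at
clip limit 0.01.  The percentiles and grid are deliberately
conservative: the goal is to normalize illumination and stretch the
dark-hole/neuropil contrast, not to invert local structure.  Constant
images are returned unchanged (equalization is undefined on a
degenerate histogram), and `clip_limit = 0` disables the local stage,
leaving a purely monotone, exactly idempotent mapping.

**Denoising.** Perona–Malik diffusion in conservative flux form with
Neumann boundaries, conductance g(|∇I|) = 1/(1 + (|∇I|/k)²), k = 0.1
intensity units, time step 0.2 (within the explicit-scheme stability
bound of 0.25), 15 iterations.  The conductance is additionally
multiplied by (1 − w·S), where S is the normalized structure-tensor
coherence of the input and w = 0.5: diffusion is suppressed on salient
(oriented, well-defined) edges so they stay sharp while flat regions are
smoothed.  w = 0 recovers classic Perona–Malik.  Because per-pixel
(rather than per-edge) suppression breaks exact flux antisymmetry, mean
conservation is guaranteed only to ~1%; tests enforce that bound.  The
output range is clipped to the input range (maximum principle).

## Three-phase segmentation

The segmentation minimizes a three-region piecewise-constant
(Chan–Vese-family) energy: data term (I − c_k)² per phase plus a
boundary penalty.  Minimization uses deterministic threshold dynamics
(MBO-style): each phase's indicator is diffused with a Gaussian
(σ = 2 px) and every pixel is reassigned to the phase minimizing
(I − c_k)² + µ(1 − G_σ ∗ χ_k), with µ = 0.05.  This scheme was chosen
over coupled level sets because it is seed-free, unconditionally stable,
vectorizes cleanly, and converges in tens of sweeps on megapixel
images; it minimizes the same energy family.

"Prior extreme" anchoring: the dark and bright phase means are not free
Chan–Vese averages but mixtures c_k = 0.5·anchor + 0.5·empirical, with
anchors at the 2nd and 98th intensity percentiles.  The background mean
stays purely empirical.  This stabilizes the two minority phases against
the dominant mid-gray background — without it, one extreme phase can
collapse into the background on low-contrast images.  Iteration stops
when fewer than 10⁻⁴ of pixels change label (or at 60 sweeps; typical
convergence is 10–25).

Phase identity is assigned after convergence by ordering the empirical
phase means (lowest → dark hole, highest → bright); ties — which occur
when a phase is empty, e.g. on two-level fluorescence images — are
broken so that the populated cluster remains background.  Images with
fewer than three distinct gray levels return a background-only map and
a warning.

## Hough rescue of faint nuclei

Nuclei whose contrast is too weak for the three-phase step are recovered
from the background with a circular Hough transform restricted to
gradient-direction voting: gradients are taken on a Gaussian-smoothed
image (σ = 2; smoothing keeps noise from scrambling the voting
directions of faint edges), and each background edge pixel with
|∇I| > 0.02 votes at ± r along its own unit gradient for every radius
in the search range (default 4–25 px).  Accumulators are smoothed
(σ = 1), normalized by circumference 2πr so votes read as "fraction of
a full circle", and pooled over adjacent radii (a real circle votes
consistently at neighbouring radii; noise does not).

Peaks above 0.07 of a full circle are extracted greedily with a 15 px
non-maximum suppression radius, then *verified photometrically*: the
disc interior (0.8 r) must be ≥ 80% background phase (this rejects vote
pile-ups from granule halos and fiber crossings) and brighter than its
1.2–1.6 r annulus by ≥ 0.10 (in enhanced-image units; CLAHE stretches
even faint nuclear contrast above this, while noise bumps stay below).
The radius is then re-estimated as the argmax of inner-minus-annulus
contrast (vote counts favour small radii when PSF-thickened edges vote
from several distances), the center is refined to the brightness
centroid of the bump, and an optional ±20% anisotropic refit
accommodates moderately elliptical nuclei.  Detections overlapping
existing bright objects by more than 50% are discarded, and no mask
leaves the image bounds.

## Object analysis

* **Perimeter** is the 4-direction Cauchy–Crofton estimate
  P = π/8 · (c₀ + c₉₀ + (c₄₅ + c₁₃₅)/√2), where c_θ counts
  foreground/background transitions along rows, columns and diagonals
  (zero-padded).  It is unbiased on discs (the shapes the nucleus gate
  selects) and ~5% low on axis-aligned rectangles, which biases a
  square's compactness to ~0.87 instead of the analytic π/4 ≈ 0.785;
  both values sit comfortably between the 0.1 and 0.5 gates, so the
  classification is insensitive to this bias.  Single-pixel objects are
  floored at perimeter 4 to avoid division blow-ups.
* **Compactness/sphericity** is 4πA/P², clipped to (0, 1.2] to tolerate
  discretization overshoot on small round masks.
* **Splitting** of touching objects uses a distance-transform watershed
  seeded by h-maxima (h = 2 px).  EDT quantization can shatter one
  plateau maximum into nearby disconnected pixels; seeds are therefore
  dilated by 3 px before labeling, which merges spurious seed pairs
  while leaving genuine cell-to-cell seeds (tens of px apart) distinct.
  Splitting partitions the parent exactly: child areas sum to the
  parent area.
* **Gates** are strict as printed: dark components are kept at
  area ≥ 1000 px; bright components below 500 px are rejected;
  compactness < 0.1 → neuropil (evaluated before splitting — an
  elongated fragment created *by* splitting is debris, not neuropil);
  compactness > 0.5 and area < 10 000 px → nucleus (evaluated after
  splitting).  Hough candidates join the nucleus pool after the
  10 000 px gate only; they bypass the 500 px pre-filter by default
  (they are, by construction, faint nuclei the bright phase missed) —
  config-exposed.
* **Cell assembly.** A nucleus is merged into the cell body whose mask
  is nearest to its centroid, if within 2 px (centroid containment
  implies distance 0); ties go to the lower body id; each nucleus
  merges at most once.  Unmatched nuclei become nucleus-only cell
  detections and still count toward cell space.
* Connectivity: 8-connectivity for objects, 4-connectivity for
  background/hole filling (Jordan-consistent pairing).

## Density features and classification

Cell PoS is the union of cell-assembly masks (cytoplasm ∪ merged
nuclei) divided by the image area; nucleus PoS uses nucleus masks only;
overlaps count once.  Neuropil density is Σ perimeter / 100.  The
classifier is `TUMOR iff cell_pos > 0.17 or nucleus_pos > 0.03` with
strict inequalities; the triggering clause is recorded.  The thresholds
are fixed defaults of the published operating point; a grid-search
re-tuning utility (maximizing Youden's J on labeled data) is provided
but never used by the validation.  Tiles with a field of view of
≥ 500 µm are split into four equal row/col halves; quarter features are
averaged arithmetically into tile features.  Both whole-image and
quartered modes are supported.

## Phantom generator

The phantoms emulate only the features the pipeline measures, not
nonlinear-optics physics:

* **Cells**: ellipses (aspect ≤ 1.5, equivalent radius 22–28 px ⇒ areas
  ~1500–2500 px, comfortably above the 1000 px gate), placed by
  rejection sampling with ≤ 5% pairwise overlap; interior intensity
  0.12 against a 0.45 background.  Each cell carries a nucleus
  (radius 0.62 × cell radius) rendered bright (0.85) with probability
  `nucleus_visibility` (default 0.5), kept ≥ 4 px inside the cell rim so
  the dark cytoplasm annulus survives PSF blurring.
* **Neuropil**: 25 smoothed random-walk polylines, width 2–5 px,
  intensity 0.8 — their compactness falls far below the 0.1 gate.
* **Granules**: 15 bright discs of radius 2–5 px (≪ 500 px), rejected by
  the size gate by design.
* **Faint nuclei** (optional): discs of radius 8–12 px at contrast
  +0.06 over background, placed in fiber-free interior regions; they
  stay below the bright-phase threshold and exist to exercise the Hough
  rescue.
* **Optics/noise**: isotropic Gaussian PSF (σ = 1 px), Poisson shot
  noise at 200 photons per unit intensity plus Gaussian read noise
  (σ = 0.01) — contrast-to-noise ≈ 7 for the cell/background step.
* **HOE channel**: the same scene geometry rendered as bright nuclei on
  a near-zero background; each nucleus appears with probability
  `uptake_uniformity`, emulating uneven dye uptake.  Fluorescence
  radiometry is not modeled.
* Determinism: identical spec + seed ⇒ bit-identical images and truth;
  placement, uptake and noise use independent streams derived from the
  one seed, so THG and HOE renderings of a scene stay paired.

Gradient mosaics interpolate a target cell PoS linearly across a
row-major tile grid and derive each tile's cell count from the mean
cell area; targets above PoS 0.45 are refused as unplaceable.  Tiles are
independent renderings (tile-to-tile content continuity is not
simulated); overlap-consistent tiles for stitching tests are produced by
cutting one rendered field with `cut_into_tiles`.

**What passing phantom tests shows — and does not.**  The phantoms
validate the measurement chain: segmentation accuracy under known
contrast, the size/compactness gates, density arithmetic, margin
localization, and the modality cross-check logic.  They do not
establish clinical performance: real tissue has textured cytoplasm,
vessels, red-blood-cell shadows, depth-dependent contrast and
out-of-focus light that no ellipse-and-polyline scene reproduces.
Claims about patient data require patient data.

## Mosaics and I/O

Stitching places tiles at fixed (1 − overlap) · tile-shape offsets
(stage-scanned acquisitions have a constant 20% overlap) with separable
linear feather blending, normalized so a cut-and-restitch round trip is
exact to float precision.  An optional ±5 px cross-correlation
refinement exists for real stage data with positioning error; it is off
by default so results depend on the layout alone.  Images are 16-bit
grayscale TIFF; label maps 8/16-bit TIFF; object tables and features
CSV; reports schema-versioned JSON whose timestamp field is omitted by
default so identical runs produce identical bytes.

## Validation sizes

The test suite and the acceptance script size their simulations for a
single CPU core: 20 phantoms (1000² px) for recall/precision in the
test suite and 8 in the acceptance script; a 1 × 6 gradient strip;
12 paired 600² px regions for the modality correlation.  Rates pool
detections across phantoms before dividing.

## Known limitations

* The compactness estimator's axis-aligned bias (above) is harmless for
  the 0.1/0.5 gates but matters if thresholds were re-tuned close to a
  polygon's analytic value.
* Faint nuclei that local equalization pushes into the bright phase are
  no longer "background" and thus invisible to the rescue step; with
  default phantom settings this affects a few percent of planted faint
  circles.
* The classifier near a density gradient can fire one tile early via
  the nucleus-density clause (nucleus PoS crosses 0.03 slightly before
  cell PoS crosses 0.17) — inherent to a two-clause rule on correlated
  densities, and within the ±1-tile localization contract.
* 2D only; 3D stacks, SHG-channel structures and vasculature are out of
  scope.
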