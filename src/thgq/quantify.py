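"""Density features and the two-threshold normal/tumor classifier.

The density of brain cells and nuclei is summarized as percentage of
space (PoS): the pixel count of the feature's union mask divided by the
image area.  PoS combines object count and size, which keeps it usable in
highly cellular tumor tissue where nucleus clumps cannot be separated.
Neuropil density is the summed perimeter (px) of detected neuropil
divided by 100.

An image is called TUMOR when its cell PoS exceeds 0.17 (separating
normal brain from low-grade-like cellularity) or its nucleus PoS exceeds
0.03 (separating normal brain from high-grade-like cellularity); both
inequalities are strict.  Large (>= 500 um) tiles are split into four
equal parts, each part is classified, and the averaged quarter features
represent the tile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import (
    CellAssembly,
    ClassificationResult,
    FeatureRecord,
    IntensityImage,
    Label,
    ObjectClass,
    SegmentedObject,
    TriggeredRule,
)

__all__ = [
    "ClassifierParams",
    "compute_pos",
    "compute_neuropil_density",
    "features_from_objects",
    "classify_image",
    "classify_mosaic",
    "compare_with_reference",
]

CELL_POS_THRESHOLD = 0.17
NUCLEUS_POS_THRESHOLD = 0.03


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds and tiling policy of the normal/tumor rule.

    Defaults are the published operating point (cell PoS 0.17, nucleus
    PoS 0.03).  ``quarter_large_tiles`` enables the four-way split for
    tiles whose field of view reaches ``large_tile_um``.
    """

    cell_pos_threshold: float = CELL_POS_THRESHOLD
    nucleus_pos_threshold: float = NUCLEUS_POS_THRESHOLD
    quarter_large_tiles: bool = True
    large_tile_um: float = 500.0

    def __post_init__(self) -> None:
        for t in (self.cell_pos_threshold, self.nucleus_pos_threshold):
            if not 0.0 < t < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")


def compute_pos(masks, image_area_px: int) -> float:
    """Percentage of space: |union of masks| / image area.

    ``masks`` is an iterable of full-image boolean rasters (or one
    stacked array); overlapping pixels count once.
    """
    if image_area_px <= 0:
        raise ValueError("image_area_px must be positive")
    union = None
    for m in masks:
        m = np.asarray(m, dtype=bool)
        union = m.copy() if union is None else (union | m)
    if union is None:
        return 0.0
    return float(union.sum()) / image_area_px


def compute_neuropil_density(neuropil: list[SegmentedObject]) -> float:
    """Summed neuropil perimeter in pixels, divided by 100."""
    for o in neuropil:
        if o.object_class is not ObjectClass.NEUROPIL:
            raise ValueError("compute_neuropil_density expects NEUROPIL objects")
    return sum(o.perimeter for o in neuropil) / 100.0


def features_from_objects(
    image_id: str,
    shape: tuple[int, int],
    assemblies: list[CellAssembly],
    objects: list[SegmentedObject],
    tile_index: tuple[int, int] | None = None,
) -> FeatureRecord:
    """Reduce classified objects to one per-image feature record.

    Cell PoS is measured over the union of cell-assembly combined masks
    (cytoplasm plus merged nuclei); nucleus PoS over NUCLEUS masks only;
    neuropil density over NEUROPIL perimeters.
    """
    area = int(shape[0] * shape[1])
    nuclei = [o for o in objects if o.object_class is ObjectClass.NUCLEUS]
    neuropil = [o for o in objects if o.object_class is ObjectClass.NEUROPIL]
    cell_pos = compute_pos((a.combined_mask for a in assemblies), area)
    nucleus_pos = compute_pos((n.full_mask(shape) for n in nuclei), area)
    return FeatureRecord(
        image_id=image_id,
        cell_pos=cell_pos,
        nucleus_pos=nucleus_pos,
        neuropil_density=compute_neuropil_density(neuropil),
        n_cells=len(assemblies),
        n_nuclei=len(nuclei),
        image_area_px=area,
        tile_index=tile_index,
    )


def classify_image(f: FeatureRecord, p: ClassifierParams | None = None) -> ClassificationResult:
    """Apply the strict-inequality OR rule to one feature record."""
    p = p or ClassifierParams()
    by_cell = f.cell_pos > p.cell_pos_threshold
    by_nucleus = f.nucleus_pos > p.nucleus_pos_threshold
    if by_cell and by_nucleus:
        rule = TriggeredRule.BOTH
    elif by_cell:
        rule = TriggeredRule.CELL_POS
    elif by_nucleus:
        rule = TriggeredRule.NUCLEUS_POS
    else:
        rule = TriggeredRule.NONE
    label = Label.TUMOR if rule is not TriggeredRule.NONE else Label.NORMAL
    return ClassificationResult(label=label, triggered_rule=rule, features=f)


def _quarters(img: IntensityImage) -> list[tuple[tuple[int, int], IntensityImage]]:
    h, w = img.pixels.shape
    hh, hw = h // 2, w // 2
    out = []
    for qi, (r0, r1) in enumerate(((0, hh), (hh, h))):
        for qj, (c0, c1) in enumerate(((0, hw), (hw, w))):
            sub = IntensityImage(img.pixels[r0:r1, c0:c1],
                                 pixel_size_um=img.pixel_size_um,
                                 channel=img.channel,
                                 provenance=f"{img.provenance}/q{qi}{qj}")
            out.append(((qi, qj), sub))
    return out


def classify_mosaic(
    tiles: list[IntensityImage],
    analyze,
    p: ClassifierParams | None = None,
    grid: tuple[int, int] | None = None,
):
    """Classify every tile of a mosaic, quartering large tiles.

    ``analyze`` is a callable mapping an IntensityImage to a
    FeatureRecord (the full pipeline; injected to keep this module free
    of segmentation concerns).  Tiles whose field of view reaches
    ``large_tile_um`` are split into four equal parts; each part is
    classified and kept, and the tile-level features are the arithmetic
    mean of its four quarters.  Returns (per-tile results, label grid,
    per-quarter results).
    """
    p = p or ClassifierParams()
    if not tiles:
        raise ValueError("no tiles given")
    shapes = {t.pixels.shape for t in tiles}
    if len(shapes) != 1:
        raise ValueError("tiles of mixed shapes")
    sizes = {t.pixel_size_um for t in tiles}
    if len(sizes) != 1:
        raise ValueError("tiles must share pixel size")
    if grid is None:
        grid = (1, len(tiles))
    if grid[0] * grid[1] != len(tiles):
        raise ValueError("grid does not match tile count")

    results: list[ClassificationResult] = []
    quarter_results: list[list[ClassificationResult]] = []
    for idx, tile in enumerate(tiles):
        fov = min(tile.field_of_view_um)
        tidx = (idx // grid[1], idx % grid[1])
        if p.quarter_large_tiles and fov >= p.large_tile_um:
            qres = []
            for _, sub in _quarters(tile):
                fq = analyze(sub)
                qres.append(classify_image(fq, p))
            quarter_results.append(qres)
            f = FeatureRecord(
                image_id=tile.provenance or f"tile{idx}",
                cell_pos=float(np.mean([q.features.cell_pos for q in qres])),
                nucleus_pos=float(np.mean([q.features.nucleus_pos for q in qres])),
                neuropil_density=float(np.mean([q.features.neuropil_density
                                                for q in qres])),
                n_cells=int(sum(q.features.n_cells for q in qres)),
                n_nuclei=int(sum(q.features.n_nuclei for q in qres)),
                image_area_px=tile.pixels.size,
                tile_index=tidx,
            )
        else:
            quarter_results.append([])
            f = analyze(tile)
            f.tile_index = tidx
        results.append(classify_image(f, p))
    label_grid = np.array([r.label.value for r in results],
                          dtype=object).reshape(grid)
    return results, label_grid, quarter_results


def compare_with_reference(
    predicted: list[ClassificationResult] | list[Label],
    truth: list[Label],
) -> dict[str, float]:
    """Sensitivity, specificity and percent agreement against reference labels.

    TUMOR is the positive class.  A denominator of zero (no positives or
    no negatives in the reference) yields NaN for the affected rate.
    """
    if not predicted or not truth:
        raise ValueError("empty label lists")
    if len(predicted) != len(truth):
        raise ValueError("prediction/truth length mismatch")
    pred = [x.label if isinstance(x, ClassificationResult) else x
            for x in predicted]
    tp = sum(1 for a, b in zip(pred, truth)
             if a is Label.TUMOR and b is Label.TUMOR)
    tn = sum(1 for a, b in zip(pred, truth)
             if a is Label.NORMAL and b is Label.NORMAL)
    fp = sum(1 for a, b in zip(pred, truth)
             if a is Label.TUMOR and b is Label.NORMAL)
    fn = sum(1 for a, b in zip(pred, truth)
             if a is Label.NORMAL and b is Label.TUMOR)
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return {
        "sensitivity": sens,
        "specificity": spec,
        "percent_agreement": (tp + tn) / len(truth),
    }


def tune_thresholds(
    features: list[FeatureRecord],
    truth: list[Label],
    cell_grid=None,
    nucleus_grid=None,
) -> ClassifierParams:
    """Grid-search thresholds maximizing Youden's J on labeled data.

    Provided as a re-tuning utility for new tissue settings; the default
    operating point (0.17 / 0.03) is used everywhere else.
    """
    if cell_grid is None:
        cell_grid = np.round(np.arange(0.05, 0.41, 0.01), 3)
    if nucleus_grid is None:
        nucleus_grid = np.round(np.arange(0.01, 0.11, 0.005), 3)
    best, best_j = None, -np.inf
    for ct in cell_grid:
        for nt in nucleus_grid:
            p = ClassifierParams(cell_pos_threshold=float(ct),
                                 nucleus_pos_threshold=float(nt))
            preds = [classify_image(f, p) for f in features]
            m = compare_with_reference(preds, truth)
            j = m["sensitivity"] + m["specificity"] - 1.0
            if j > best_j:
                best_j, best = j, p
    return best
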