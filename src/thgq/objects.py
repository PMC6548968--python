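"""Object analysis: from phase maps to classified cells, nuclei, neuropil.

Dark-hole components are hole-filled, split at necks, and kept as brain
cells / cytoplasm when they reach 1000 px (~6 um x 6 um at ~0.3 um/px).
Bright components below 500 px (lipofuscin granules, debris) are ignored;
of the rest, fiber-like components with compactness below 0.1 become
neuropil, and — after splitting slightly touching objects — components
with compactness above 0.5 and below 10 000 px become nuclei, pooled with
the nucleus candidates rescued from the background by the Hough step.
Dark cell bodies are finally merged with the bright nuclei they contain
to form full brain-cell detections.

Compactness ("sphericity") is the isoperimetric quotient 4*pi*A/P^2 with
P estimated by a 4-direction Cauchy-Crofton intercept count, which is
unbiased on discs (the shapes the 0.5 gate selects) and slightly
underestimates axis-aligned polygon perimeters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as cc_label
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .datatypes import (
    BRIGHT,
    DARK_HOLE,
    CellAssembly,
    ObjectClass,
    PhaseOrigin,
    SegmentedObject,
)

__all__ = [
    "ObjectParams",
    "compute_perimeter",
    "compute_sphericity",
    "make_object",
    "split_touching",
    "extract_dark_objects",
    "classify_bright_objects",
    "assemble_cells",
    "dark_object_retained",
    "bright_object_class",
]

# size/shape gates of the published workflow (strict inequalities)
MIN_CELL_AREA_PX = 1000
MIN_BRIGHT_AREA_PX = 500
MAX_NUCLEUS_AREA_PX = 10_000
NEUROPIL_SPHERICITY_MAX = 0.1
NUCLEUS_SPHERICITY_MIN = 0.5

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class ObjectParams:
    """Tunables of the object-analysis stage.

    ``split_h`` is the h-maxima depth (px) used to suppress shallow
    distance-transform maxima before watershed splitting; larger values
    split less.  ``hough_bypass_min_area`` controls whether Hough nucleus
    candidates face the 500 px bright-object pre-filter (they do not by
    default: they are, by construction, faint nuclei that the bright
    phase missed).
    """

    split_h: float = 2.0
    merge_distance_px: float = 2.0
    hough_bypass_min_area: bool = True


def compute_perimeter(mask: np.ndarray) -> float:
    """Cauchy-Crofton boundary length of a binary mask.

    Counts foreground/background transitions along rows, columns and both
    diagonals (zero-padded, so image-edge boundaries count) and combines
    them as P = pi/8 * (c0 + c90 + (c45 + c135)/sqrt(2)).  Exact 2*pi*r on
    ideal discs in expectation; ~5% low on axis-aligned rectangles.
    A single-pixel object returns the 4-edge lower bound.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return 0.0
    p = np.pad(m, 1).astype(np.int8)
    c0 = np.count_nonzero(p[:, 1:] != p[:, :-1])
    c90 = np.count_nonzero(p[1:, :] != p[:-1, :])
    c45 = np.count_nonzero(p[1:, 1:] != p[:-1, :-1])
    c135 = np.count_nonzero(p[1:, :-1] != p[:-1, 1:])
    per = np.pi / 8.0 * (c0 + c90 + (c45 + c135) / _SQRT2)
    return float(max(per, 4.0)) if m.sum() == 1 else float(per)


def compute_sphericity(mask_or_area, perimeter: float | None = None) -> float:
    """Isoperimetric quotient 4*pi*A/P^2, clipped to (0, 1.2].

    Accepts either a binary mask or an (area, perimeter) pair.  The clip
    ceiling tolerates discretization overshoot on small near-circular
    masks; the quotient decreases with elongation at fixed area.
    """
    if perimeter is None:
        mask = np.asarray(mask_or_area, dtype=bool)
        area = float(mask.sum())
        perimeter = compute_perimeter(mask)
    else:
        area = float(mask_or_area)
    if area <= 0 or perimeter <= 0:
        raise ValueError("sphericity needs positive area and perimeter")
    return float(np.clip(4.0 * np.pi * area / perimeter**2, 1e-12, 1.2))


def object_from_local(
    local_mask: np.ndarray,
    offset: tuple[int, int],
    oid: int,
    phase_origin: PhaseOrigin,
    object_class: ObjectClass,
) -> SegmentedObject:
    """Build a SegmentedObject from a bbox-local mask and its offset."""
    local = np.asarray(local_mask, dtype=bool)
    area = int(local.sum())
    per = compute_perimeter(local)
    ys, xs = np.nonzero(local)
    return SegmentedObject(
        id=oid,
        mask=local.copy(),
        offset=(int(offset[0]), int(offset[1])),
        area=area,
        perimeter=per,
        sphericity=compute_sphericity(area, per),
        centroid=(float(ys.mean()) + offset[0], float(xs.mean()) + offset[1]),
        phase_origin=phase_origin,
        object_class=object_class,
    )


def make_object(
    full_mask: np.ndarray,
    oid: int,
    phase_origin: PhaseOrigin,
    object_class: ObjectClass,
) -> SegmentedObject:
    """Build a SegmentedObject (bbox-local mask) from a full-image mask."""
    rows = np.any(full_mask, axis=1)
    cols = np.any(full_mask, axis=0)
    r0, r1 = np.where(rows)[0][[0, -1]]
    c0, c1 = np.where(cols)[0][[0, -1]]
    local = full_mask[r0 : r1 + 1, c0 : c1 + 1]
    return object_from_local(local, (int(r0), int(c0)), oid,
                             phase_origin, object_class)


def split_touching(mask: np.ndarray, h: float = 2.0) -> np.ndarray:
    """Separate slightly touching objects inside one binary mask.

    Distance-transform-seeded watershed with h-maxima suppression of
    shallow seeds.  Returns an integer label image that partitions the
    mask exactly: child areas sum to the parent area and distinct parents
    are never merged.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return np.zeros(m.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(m)
    peaks = h_maxima(dist, h)
    # EDT quantization can shatter one plateau maximum into nearby
    # disconnected pixels; merge peaks within a few px before labeling
    peaks = ndi.binary_dilation(
        peaks, structure=ndi.generate_binary_structure(2, 2), iterations=3)
    markers = cc_label(peaks, connectivity=2)
    if markers.max() <= 1:
        return cc_label(m, connectivity=2).astype(np.int32)
    labels = watershed(-dist, markers=markers, mask=m)
    return labels.astype(np.int32)


# -- pure gate predicates (the published thresholds, strict as printed) ----

def dark_object_retained(area: int) -> bool:
    """Dark holes smaller than 1000 px are ignored."""
    return area >= MIN_CELL_AREA_PX


def bright_object_class(area: int, sphericity: float) -> ObjectClass:
    """Classify one bright component by the size and compactness gates.

    < 500 px -> rejected; compactness < 0.1 -> neuropil; compactness
    > 0.5 and area < 10 000 px -> nucleus; everything else rejected.
    """
    if area < MIN_BRIGHT_AREA_PX:
        return ObjectClass.GRANULE_OR_REJECTED
    if sphericity < NEUROPIL_SPHERICITY_MAX:
        return ObjectClass.NEUROPIL
    if sphericity > NUCLEUS_SPHERICITY_MIN and area < MAX_NUCLEUS_AREA_PX:
        return ObjectClass.NUCLEUS
    return ObjectClass.GRANULE_OR_REJECTED


# -- stage operations ------------------------------------------------------

def extract_dark_objects(phases, p: ObjectParams | None = None) -> list[SegmentedObject]:
    """Hole-fill, split and size-filter the dark-hole phase.

    Components surviving the 1000 px gate are tagged CELL_BODY.  Hole
    filling completes cytoplasm annuli around bright nuclei; splitting
    separates slightly touching cells at necks.
    """
    p = p or ObjectParams()
    dark = phases.mask(DARK_HOLE)
    if not dark.any():
        return []
    filled = ndi.binary_fill_holes(dark)  # 4-connected background
    labels = split_touching(filled, h=p.split_h)
    out: list[SegmentedObject] = []
    oid = 0
    for lbl, slc in enumerate(ndi.find_objects(labels), start=1):
        if slc is None:
            continue
        local = labels[slc] == lbl
        if not dark_object_retained(int(local.sum())):
            continue
        out.append(object_from_local(local, (slc[0].start, slc[1].start),
                                     oid, PhaseOrigin.DARK_HOLE,
                                     ObjectClass.CELL_BODY))
        oid += 1
    return out


def classify_bright_objects(
    phases,
    hough: list[SegmentedObject] | None = None,
    p: ObjectParams | None = None,
) -> list[SegmentedObject]:
    """Sort bright components into neuropil / nuclei / rejected.

    The 500 px pre-filter applies first; fiber-like survivors (compactness
    < 0.1) become neuropil; the rest are split (touching nuclei) and the
    nucleus gate (compactness > 0.5, area < 10 000 px) applies to each
    child.  Hough nucleus candidates are appended to the nucleus pool
    after the same area gate (bypassing the 500 px pre-filter by default).
    """
    p = p or ObjectParams()
    bright = phases.mask(BRIGHT)
    out: list[SegmentedObject] = []
    oid = 0
    comp = cc_label(bright, connectivity=2)
    for lbl, slc in enumerate(ndi.find_objects(comp), start=1):
        if slc is None:
            continue
        local = comp[slc] == lbl
        off = (slc[0].start, slc[1].start)
        area = int(local.sum())
        if area < MIN_BRIGHT_AREA_PX:
            out.append(object_from_local(local, off, oid, PhaseOrigin.BRIGHT,
                                         ObjectClass.GRANULE_OR_REJECTED))
            oid += 1
            continue
        obj = object_from_local(local, off, oid, PhaseOrigin.BRIGHT,
                                ObjectClass.GRANULE_OR_REJECTED)
        if obj.sphericity < NEUROPIL_SPHERICITY_MAX:
            obj.object_class = ObjectClass.NEUROPIL
            out.append(obj)
            oid += 1
            continue
        # split slightly touching nuclei, then gate each child
        children = split_touching(local, h=p.split_h)
        for child_lbl, child_slc in enumerate(ndi.find_objects(children),
                                              start=1):
            if child_slc is None:
                continue
            cm = children[child_slc] == child_lbl
            coff = (off[0] + child_slc[0].start, off[1] + child_slc[1].start)
            cobj = object_from_local(cm, coff, oid, PhaseOrigin.BRIGHT,
                                     ObjectClass.GRANULE_OR_REJECTED)
            cobj.object_class = bright_object_class(cobj.area, cobj.sphericity)
            if cobj.object_class is ObjectClass.NEUROPIL:
                # the neuropil call is made on unsplit fibers only; a split
                # child this elongated is debris, not neuropil
                cobj.object_class = ObjectClass.GRANULE_OR_REJECTED
            out.append(cobj)
            oid += 1
    if hough:
        for cand in hough:
            keep = cand.area < MAX_NUCLEUS_AREA_PX and (
                p.hough_bypass_min_area or cand.area >= MIN_BRIGHT_AREA_PX
            )
            obj = SegmentedObject(
                id=oid, mask=cand.mask.copy(), offset=cand.offset,
                area=cand.area, perimeter=cand.perimeter,
                sphericity=cand.sphericity, centroid=cand.centroid,
                phase_origin=PhaseOrigin.HOUGH,
                object_class=(ObjectClass.NUCLEUS if keep
                              else ObjectClass.GRANULE_OR_REJECTED),
            )
            out.append(obj)
            oid += 1
    return out


def assemble_cells(
    cell_bodies: list[SegmentedObject],
    nuclei: list[SegmentedObject],
    shape: tuple[int, int],
    p: ObjectParams | None = None,
) -> list[CellAssembly]:
    """Merge dark cell bodies with the bright nuclei they contain.

    A nucleus joins a body when its centroid falls inside the body mask or
    within ``merge_distance_px`` of it; the nearest body wins, ties going
    to the lower body id.  Unmatched nuclei become nucleus-only
    assemblies — faint cells may surface only through their nucleus and
    still count toward cell space.
    """
    p = p or ObjectParams()
    # exact point-to-mask distances via per-body boundary pixel coordinates
    body_pixels = {}
    for b in cell_bodies:
        ys, xs = np.nonzero(b.mask)
        body_pixels[b.id] = (ys + b.offset[0], xs + b.offset[1])
    assignments: dict[int, list[SegmentedObject]] = {b.id: [] for b in cell_bodies}
    standalone: list[SegmentedObject] = []
    for nuc in nuclei:
        r = min(max(nuc.centroid[0], 0.0), shape[0] - 1.0)
        c = min(max(nuc.centroid[1], 0.0), shape[1] - 1.0)
        best_id, best_d = None, np.inf
        for b in cell_bodies:  # ordered by id: ties keep the lower id
            ys, xs = body_pixels[b.id]
            d = float(np.sqrt(((ys - r) ** 2 + (xs - c) ** 2).min()))
            if d <= p.merge_distance_px and d < best_d:
                best_id, best_d = b.id, d
        if best_id is None:
            standalone.append(nuc)
        else:
            assignments[best_id].append(nuc)

    out: list[CellAssembly] = []
    cid = 0
    for b in cell_bodies:
        combined = b.full_mask(shape)
        nuc_ids = []
        for nuc in assignments[b.id]:
            combined |= nuc.full_mask(shape)
            nuc_ids.append(nuc.id)
        ys, xs = np.nonzero(combined)
        out.append(CellAssembly(cid, b.id, nuc_ids, combined,
                                int(combined.sum()),
                                (float(ys.mean()), float(xs.mean()))))
        cid += 1
    for nuc in standalone:
        m = nuc.full_mask(shape)
        out.append(CellAssembly(cid, None, [nuc.id], m, int(m.sum()),
                                nuc.centroid))
        cid += 1
    return out
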