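"""Three-phase segmentation and Hough-based nucleus rescue.

A preprocessed THG image is partitioned into three phases: dark holes
(cell bodies / cytoplasm), bright objects (nuclei, neuropil fibers,
granules) and the remaining background.  The partition minimizes a
piecewise-constant three-region energy (Chan-Vese family) whose dark and
bright region means are softly anchored to the image's intensity extremes,
stabilizing both phases against the dominant mid-gray background.  The
minimization uses deterministic threshold dynamics: indicator functions
are diffused and every pixel is reassigned to the phase with the lowest
data + boundary cost, iterated to convergence.

Nuclei whose contrast is too weak for the three-phase step end up labeled
background.  A modified circular Hough transform then scans only the
background: each edge pixel votes along its own gradient direction (both
orientations), concentrating votes of circular structures onto their
centers; accumulator peaks become filled nucleus-candidate discs, with an
optional moderately elliptical refit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .datatypes import (
    BACKGROUND,
    BRIGHT,
    DARK_HOLE,
    IntensityImage,
    ObjectClass,
    PhaseOrigin,
    SegmentedObject,
)
from .objects import make_object, object_from_local

__all__ = [
    "ThreePhaseParams",
    "HoughParams",
    "PhaseLabelMap",
    "segment_three_phase",
    "rescue_nuclei_hough",
]


@dataclass
class PhaseLabelMap:
    """Per-pixel phase labels {0: background, 1: dark hole, 2: bright}."""

    labels: np.ndarray
    source: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        bad = ~np.isin(self.labels, (BACKGROUND, DARK_HOLE, BRIGHT))
        if bad.any():
            raise ValueError("phase map contains labels outside {0, 1, 2}")

    def mask(self, phase: int) -> np.ndarray:
        return self.labels == phase


@dataclass(frozen=True)
class ThreePhaseParams:
    """Settings of the three-phase piecewise-constant segmentation.

    ``prior_extreme_percentiles`` give the intensity percentiles the dark
    and bright phase means are anchored to; ``anchor_weight`` in [0, 1]
    mixes that anchor with the empirical phase mean (0 = plain Chan-Vese
    means).  ``smoothness_mu`` scales the boundary penalty and
    ``smoothing_sigma`` the indicator diffusion that carries it.
    Iteration stops once the fraction of pixels changing label falls
    below ``convergence_tol``.
    """

    max_iterations: int = 60
    convergence_tol: float = 1e-4
    smoothness_mu: float = 0.05
    smoothing_sigma: float = 2.0
    prior_extreme_percentiles: tuple[float, float] = (2.0, 98.0)
    anchor_weight: float = 0.5
    reinit_interval: int = 10  # phase means refreshed every iteration; kept for API

    def __post_init__(self) -> None:
        lo, hi = self.prior_extreme_percentiles
        if not 0.0 < lo < hi < 100.0:
            raise ValueError("prior extreme percentiles must satisfy 0 < lo < hi < 100")
        if not 0.0 < self.convergence_tol < 1.0:
            raise ValueError("convergence_tol must lie in (0, 1)")
        if not 0.0 <= self.anchor_weight <= 1.0:
            raise ValueError("anchor_weight must lie in [0, 1]")


@dataclass(frozen=True)
class HoughParams:
    """Gradient-direction-restricted circular Hough settings.

    Gradients are taken on a Gaussian-smoothed image (``gradient_sigma``)
    so that noise does not scramble the voting directions of faint edges.
    ``accumulator_peak_threshold`` is relative: the fraction of a full
    circle's circumference that must have voted for a peak to count.
    Accepted peaks are verified before becoming detections: the disc
    interior must be mostly background phase (``min_inner_background``)
    and brighter than its surrounding annulus by ``min_contrast`` —
    rejecting vote pile-ups from granule halos, fiber crossings and
    noise.  ``allow_elliptical`` refits accepted peaks with up to +/-20%
    anisotropic radii, accommodating moderately elliptical nuclei.
    """

    radius_range: tuple[int, int] = (4, 25)
    edge_threshold: float = 0.02
    gradient_sigma: float = 2.0
    accumulator_peak_threshold: float = 0.07
    min_center_distance: int = 15
    min_contrast: float = 0.10
    min_inner_background: float = 0.8
    allow_elliptical: bool = True

    def __post_init__(self) -> None:
        r_min, r_max = self.radius_range
        if not 0 < r_min < r_max:
            raise ValueError("require 0 < r_min < r_max")
        if self.edge_threshold <= 0 or self.accumulator_peak_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_center_distance < 1:
            raise ValueError("min_center_distance must be >= 1")
        if not 0.0 <= self.min_inner_background <= 1.0:
            raise ValueError("min_inner_background must lie in [0, 1]")


def segment_three_phase(
    img: IntensityImage, p: ThreePhaseParams | None = None
) -> PhaseLabelMap:
    """Partition a preprocessed image into dark / bright / background.

    Phase identity is fixed by the intensity ordering of the converged
    region means (lowest -> dark hole, highest -> bright), so the result
    does not depend on internal label bookkeeping.  An image with fewer
    than three distinct intensity levels cannot support three phases: a
    background-only map is returned with ``degenerate=True`` and a
    warning.
    """
    p = p or ThreePhaseParams()
    x = img.pixels
    if np.unique(x).size < 3:
        warnings.warn("image has < 3 distinct intensity levels; "
                      "returning background-only segmentation")
        return PhaseLabelMap(np.zeros(x.shape, dtype=np.uint8),
                             source=img.provenance, degenerate=True)

    lo, hi = np.percentile(x, p.prior_extreme_percentiles)
    mid = np.median(x)
    anchors = np.array([mid, lo, hi])  # background, dark, bright
    means = anchors.copy()

    # initial assignment: nearest anchored mean (deterministic, seed-free)
    labels = np.argmin((x[..., None] - means[None, None, :]) ** 2, axis=-1)
    n_px = x.size
    w = p.anchor_weight
    for _ in range(p.max_iterations):
        for k in (0, 1, 2):
            sel = labels == k
            emp = x[sel].mean() if sel.any() else anchors[k]
            # dark/bright means are softly anchored to the intensity
            # extremes; the background mean is purely empirical
            means[k] = w * anchors[k] + (1 - w) * emp if k else emp
        # threshold dynamics: diffused indicators carry the boundary penalty
        cost = np.empty((3,) + x.shape)
        for k in (0, 1, 2):
            chi = ndi.gaussian_filter((labels == k).astype(np.float64),
                                      p.smoothing_sigma, mode="nearest")
            cost[k] = (x - means[k]) ** 2 + p.smoothness_mu * (1.0 - chi)
        new_labels = np.argmin(cost, axis=0)
        changed = np.count_nonzero(new_labels != labels) / n_px
        labels = new_labels
        if changed < p.convergence_tol:
            break

    # map internal labels to phase codes by intensity ordering; ties in
    # mean (e.g. an empty extreme phase in a two-level image) go to the
    # smaller cluster so the populated one stays background
    final_means = np.array([x[labels == k].mean() if (labels == k).any()
                            else means[k] for k in range(3)])
    counts = np.array([(labels == k).sum() for k in range(3)])
    dark = min(range(3), key=lambda k: (final_means[k], counts[k]))
    rest = [k for k in range(3) if k != dark]
    bright = max(rest, key=lambda k: (final_means[k], -counts[k]))
    middle = next(k for k in rest if k != bright)
    remap = np.empty(3, dtype=np.uint8)
    remap[dark] = DARK_HOLE
    remap[middle] = BACKGROUND
    remap[bright] = BRIGHT
    return PhaseLabelMap(remap[labels], source=img.provenance)


def _smoothed_gradients(x: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    gy = ndi.gaussian_filter(x, sigma, order=(1, 0), mode="nearest")
    gx = ndi.gaussian_filter(x, sigma, order=(0, 1), mode="nearest")
    return gy, gx


def _directional_accumulators(
    x: np.ndarray,
    background: np.ndarray,
    p: HoughParams,
    directions: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vote each background edge pixel along +/- its gradient direction.

    Returns the stacked per-radius accumulators (normalized by
    circumference, pooled over adjacent radii) and the radius vector.
    ``directions`` optionally overrides the per-edge-pixel unit vectors
    (used to demonstrate that directional voting concentrates votes).
    """
    gy, gx = _smoothed_gradients(x, p.gradient_sigma)
    mag = np.hypot(gy, gx)
    edges = (mag > p.edge_threshold) & background
    h, w = x.shape
    radii = np.arange(p.radius_range[0], p.radius_range[1] + 1)
    acc = np.zeros((radii.size, h, w), dtype=np.float64)
    ey, ex = np.nonzero(edges)
    if ey.size == 0:
        return acc, radii
    if directions is None:
        uy = gy[ey, ex] / mag[ey, ex]
        ux = gx[ey, ex] / mag[ey, ex]
    else:
        uy, ux = directions
    for i, r in enumerate(radii):
        for sign in (1.0, -1.0):
            cy = np.round(ey + sign * r * uy).astype(np.intp)
            cx = np.round(ex + sign * r * ux).astype(np.intp)
            ok = (cy >= 0) & (cy < h) & (cx >= 0) & (cx < w)
            np.add.at(acc[i], (cy[ok], cx[ok]), 1.0)
        ndi.gaussian_filter(acc[i], 1.0, output=acc[i], mode="constant")
        acc[i] /= 2.0 * np.pi * r  # fraction of circumference that voted
    # a real circle's votes persist across neighbouring radii; pooling
    # sharpens true peaks relative to noise
    return ndi.uniform_filter1d(acc, size=3, axis=0, mode="nearest"), radii


def _refine_center(votes: np.ndarray, cy: int, cx: int,
                   half: int = 3) -> tuple[int, int]:
    """Shift a raw argmax peak to the vote-weighted centroid nearby.

    Rounding of vote targets biases the raw argmax by a few px; the
    centroid over a small window recovers the center of vote mass.
    """
    h, w = votes.shape
    r0, r1 = max(0, cy - half), min(h, cy + half + 1)
    c0, c1 = max(0, cx - half), min(w, cx + half + 1)
    win = votes[r0:r1, c0:c1]
    wts = win - win.min()
    if wts.sum() <= 0:
        return cy, cx
    yy, xx = np.mgrid[r0:r1, c0:c1]
    return (int(round((wts * yy).sum() / wts.sum())),
            int(round((wts * xx).sum() / wts.sum())))


def _best_ring_radius(
    x: np.ndarray,
    background: np.ndarray,
    cy: int,
    cx: int,
    radii: np.ndarray,
) -> float:
    """Re-estimate a detection's radius by inner-vs-annulus contrast.

    Thick (PSF-blurred) edges let small radii win the vote count; the
    radius whose disc-minus-surround contrast is maximal is a far better
    scale estimate for a faint blob.
    """
    best_r, best_score = float(radii[0]), -np.inf
    for r in radii:
        h, w = x.shape
        rr = int(np.ceil(1.6 * r)) + 1
        r0, r1 = max(0, cy - rr), min(h, cy + rr + 1)
        c0, c1 = max(0, cx - rr), min(w, cx + rr + 1)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        inner = (d2 <= (0.8 * r) ** 2) & background[r0:r1, c0:c1]
        annulus = (d2 >= (1.2 * r) ** 2) & (d2 <= (1.6 * r) ** 2) & \
            background[r0:r1, c0:c1]
        if inner.sum() < 5 or annulus.sum() < 10:
            continue
        score = x[r0:r1, c0:c1][inner].mean() - x[r0:r1, c0:c1][annulus].mean()
        if score > best_score:
            best_score, best_r = score, float(r)
    return best_r


def _photometric_center(
    x: np.ndarray,
    background: np.ndarray,
    cy: int,
    cx: int,
    r: float,
) -> tuple[float, float]:
    """Center of brightness mass of the faint disc around a verified peak.

    The accumulator argmax carries a couple px of rounding/direction
    bias; the intensity-weighted centroid of the above-surround
    brightness inside the disc is a better center estimate.
    """
    h, w = x.shape
    rr = int(np.ceil(1.6 * r)) + 1
    r0, r1 = max(0, cy - rr), min(h, cy + rr + 1)
    c0, c1 = max(0, cx - rr), min(w, cx + rr + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    annulus = (d2 >= (1.2 * r) ** 2) & (d2 <= (1.6 * r) ** 2) & \
        background[r0:r1, c0:c1]
    if annulus.sum() < 10:
        return float(cy), float(cx)
    base = x[r0:r1, c0:c1][annulus].mean()
    wts = np.clip(x[r0:r1, c0:c1] - base, 0, None) * \
        ((d2 <= (1.2 * r) ** 2) & background[r0:r1, c0:c1])
    if wts.sum() <= 0:
        return float(cy), float(cx)
    return (float((wts * yy).sum() / wts.sum()),
            float((wts * xx).sum() / wts.sum()))


def _verify_peak(
    x: np.ndarray,
    background: np.ndarray,
    cy: int,
    cx: int,
    r: float,
    p: HoughParams,
) -> bool:
    """Photometric check of an accumulator peak.

    A genuine faint nucleus is a background-phase disc brighter than its
    local surround; granule halos and fiber crossings fail the interior
    purity test, noise bumps fail the contrast test.
    """
    h, w = x.shape
    rr = int(np.ceil(1.6 * r)) + 1
    r0, r1 = max(0, cy - rr), min(h, cy + rr + 1)
    c0, c1 = max(0, cx - rr), min(w, cx + rr + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    inner = d2 <= (0.8 * r) ** 2
    annulus = (d2 >= (1.2 * r) ** 2) & (d2 <= (1.6 * r) ** 2) & \
        background[r0:r1, c0:c1]
    if inner.sum() == 0 or annulus.sum() < 10:
        return False
    if background[r0:r1, c0:c1][inner].mean() < p.min_inner_background:
        return False
    contrast = x[r0:r1, c0:c1][inner].mean() - x[r0:r1, c0:c1][annulus].mean()
    return contrast > p.min_contrast


def _refit_ellipse(
    mag: np.ndarray, cy: int, cx: int, r: float, p: HoughParams
) -> tuple[float, float]:
    """Anisotropic +/-20% radius refit around an accepted peak.

    Picks the (r_row, r_col) pair in the tolerance band whose elliptical
    ring has the highest mean gradient magnitude.
    """
    h, w = mag.shape
    theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    best = (r, r)
    best_score = -np.inf
    scales = np.linspace(0.8, 1.2, 5)
    for sr in scales:
        for sc in scales:
            ry, rx = r * sr, r * sc
            py = np.clip(np.round(cy + ry * np.sin(theta)).astype(int), 0, h - 1)
            px = np.clip(np.round(cx + rx * np.cos(theta)).astype(int), 0, w - 1)
            score = mag[py, px].mean()
            if score > best_score:
                best_score = score
                best = (ry, rx)
    return best


def rescue_nuclei_hough(
    img: IntensityImage,
    phases: PhaseLabelMap,
    p: HoughParams | None = None,
    start_id: int = 0,
) -> list[SegmentedObject]:
    """Detect faint round/elliptical nuclei missed by the 3-phase step.

    Operates exclusively on background-labeled pixels.  Accumulator peaks
    above the relative vote threshold become filled disc (or moderately
    elliptical) masks; detections overlapping existing bright objects by
    more than 50% are discarded, and no mask leaves the image bounds.
    """
    p = p or HoughParams()
    background = phases.mask(BACKGROUND)
    if not background.any():
        return []
    x = img.pixels
    acc, radii = _directional_accumulators(x, background, p)
    if acc.max() <= 0:
        return []

    # greedy peak extraction with non-max suppression across radii
    best_r_idx = np.argmax(acc, axis=0)
    best_votes = np.take_along_axis(acc, best_r_idx[None], axis=0)[0]
    candidates = np.argwhere(best_votes > p.accumulator_peak_threshold)
    if candidates.size == 0:
        return []
    order = np.argsort(best_votes[candidates[:, 0], candidates[:, 1]])[::-1]
    candidates = candidates[order]
    accepted: list[tuple[int, int, float]] = []
    for cy, cx in candidates:
        if any((cy - ay) ** 2 + (cx - ax) ** 2 < p.min_center_distance**2
               for ay, ax, _ in accepted):
            continue
        cy, cx = _refine_center(best_votes, int(cy), int(cx))
        if any((cy - ay) ** 2 + (cx - ax) ** 2 < p.min_center_distance**2
               for ay, ax, _ in accepted):
            continue
        accepted.append((cy, cx, float(radii[best_r_idx[cy, cx]])))

    bright = phases.mask(BRIGHT)
    h, w = x.shape
    out: list[SegmentedObject] = []
    oid = start_id
    if p.allow_elliptical and accepted:
        gy, gx = _smoothed_gradients(x, p.gradient_sigma)
        mag = np.hypot(gy, gx)
    for cy, cx, r in accepted:
        r = _best_ring_radius(x, background, cy, cx, radii)
        if not _verify_peak(x, background, cy, cx, r, p):
            continue
        cy, cx = _photometric_center(x, background, cy, cx, r)
        cyi, cxi = int(round(cy)), int(round(cx))
        r = _best_ring_radius(x, background, cyi, cxi, radii)
        if not _verify_peak(x, background, cyi, cxi, r, p):
            continue
        if p.allow_elliptical:
            ry, rx = _refit_ellipse(mag, cy, cx, r, p)
        else:
            ry = rx = r
        # local stamp of the filled ellipse, clipped to image bounds
        r0, r1 = max(0, int(cy - ry) - 1), min(h, int(cy + ry) + 2)
        c0, c1 = max(0, int(cx - rx) - 1), min(w, int(cx + rx) + 2)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        local = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        if not local.any():
            continue
        overlap = (local & bright[r0:r1, c0:c1]).sum() / local.sum()
        if overlap > 0.5:
            continue
        obj = object_from_local(local, (r0, c0), oid, PhaseOrigin.HOUGH,
                                ObjectClass.NUCLEUS_CANDIDATE)
        out.append(obj)
        oid += 1
    return out
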