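"""Core value types shared across the quantification workflow.

The unit of analysis is a single 2D grayscale THG (or HOE fluorescence)
image, optionally one tile of a larger mosaic.  Segmentation produces a
three-phase label map (dark holes / bright objects / background); object
analysis turns phases into classified connected components; quantification
reduces objects to per-image density features and a normal/tumor call.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "BACKGROUND",
    "DARK_HOLE",
    "BRIGHT",
    "Phase",
    "ObjectClass",
    "PhaseOrigin",
    "IntensityImage",
    "SegmentedObject",
    "CellAssembly",
    "FeatureRecord",
    "Label",
    "TriggeredRule",
    "ClassificationResult",
]

# Phase codes of the 3-phase segmentation label map.
BACKGROUND = 0
DARK_HOLE = 1
BRIGHT = 2


class Phase(enum.IntEnum):
    BACKGROUND = BACKGROUND
    DARK_HOLE = DARK_HOLE
    BRIGHT = BRIGHT


class ObjectClass(str, enum.Enum):
    CELL_BODY = "CELL_BODY"
    NUCLEUS = "NUCLEUS"
    NEUROPIL = "NEUROPIL"
    GRANULE_OR_REJECTED = "GRANULE_OR_REJECTED"
    NUCLEUS_CANDIDATE = "NUCLEUS_CANDIDATE"


class PhaseOrigin(str, enum.Enum):
    DARK_HOLE = "DARK_HOLE"
    BRIGHT = "BRIGHT"
    HOUGH = "HOUGH"


@dataclass
class IntensityImage:
    """A 2D non-negative grayscale raster with physical pixel size.

    Parameters
    ----------
    pixels
        2D float array of intensities.  Preprocessed images live in [0, 1].
    pixel_size_um
        Edge length of one pixel in micrometres (~0.3 for a 300x300 um
        field sampled at ~1000x1000 px).
    channel
        One of ``"THG"``, ``"SHG"``, ``"HOE"``.
    provenance
        Free-form source description (path, tile index).
    """

    pixels: np.ndarray
    pixel_size_um: float = 0.3
    channel: str = "THG"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("IntensityImage requires a 2D array")
        if self.pixels.shape[0] < 64 or self.pixels.shape[1] < 64:
            raise ValueError("image must be at least 64x64 px")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")
        if self.pixels.min() < 0:
            raise ValueError("image contains negative intensities")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def field_of_view_um(self) -> tuple[float, float]:
        h, w = self.pixels.shape
        return (h * self.pixel_size_um, w * self.pixel_size_um)


@dataclass
class SegmentedObject:
    """One connected component with shape statistics.

    ``mask`` is stored in bounding-box-local coordinates; ``offset`` is the
    (row, col) of the bounding box origin in the source image.  ``area`` is
    the pixel count, ``perimeter`` the Crofton-style boundary length, and
    ``sphericity`` the isoperimetric quotient 4*pi*A/P^2 used to gate
    nuclei (> 0.5) against fiber-like neuropil (< 0.1).
    """

    id: int
    mask: np.ndarray
    offset: tuple[int, int]
    area: int
    perimeter: float
    sphericity: float
    centroid: tuple[float, float]
    phase_origin: PhaseOrigin
    object_class: ObjectClass

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Paint this object's mask into a full-size boolean raster."""
        out = np.zeros(shape, dtype=bool)
        r0, c0 = self.offset
        h, w = self.mask.shape
        out[r0 : r0 + h, c0 : c0 + w] = self.mask
        return out


@dataclass
class CellAssembly:
    """A brain-cell detection: dark cytoplasm merged with bright nuclei.

    Nucleus-only assemblies (no cytoplasm matched) are legal: faint cells
    can surface only through their nucleus and still count toward the
    cell percentage-of-space.
    """

    cell_id: int
    cytoplasm_object_id: Optional[int]
    nucleus_object_ids: list[int]
    combined_mask: np.ndarray  # full-image boolean raster
    combined_area: int
    centroid: tuple[float, float]


@dataclass
class FeatureRecord:
    """Per-image (or per-tile/quarter) density features.

    ``cell_pos`` / ``nucleus_pos`` are percentage-of-space fractions: the
    pixel count of the feature's union mask divided by the image area.
    ``neuropil_density`` is the summed neuropil perimeter in pixels
    divided by 100.
    """

    image_id: str
    cell_pos: float
    nucleus_pos: float
    neuropil_density: float
    n_cells: int
    n_nuclei: int
    image_area_px: int
    tile_index: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.cell_pos <= 1.0 and 0.0 <= self.nucleus_pos <= 1.0):
            raise ValueError("PoS fractions must lie in [0, 1]")
        if self.neuropil_density < 0:
            raise ValueError("neuropil_density must be >= 0")


class Label(str, enum.Enum):
    NORMAL = "NORMAL"
    TUMOR = "TUMOR"


class TriggeredRule(str, enum.Enum):
    CELL_POS = "CELL_POS"
    NUCLEUS_POS = "NUCLEUS_POS"
    BOTH = "BOTH"
    NONE = "NONE"


@dataclass
class ClassificationResult:
    """Normal/tumor call for one image or tile, with the rule that fired."""

    label: Label
    triggered_rule: TriggeredRule
    features: FeatureRecord

    def __post_init__(self) -> None:
        tumor = self.label is Label.TUMOR
        fired = self.triggered_rule is not TriggeredRule.NONE
        if tumor != fired:
            raise ValueError("label and triggered_rule are inconsistent")
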