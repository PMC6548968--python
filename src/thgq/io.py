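"""Image, report and configuration I/O plus QC overlay rendering."""

from __future__ import annotations

import dataclasses
import json
import typing
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from skimage.segmentation import find_boundaries

from .datatypes import (
    ClassificationResult,
    FeatureRecord,
    IntensityImage,
    ObjectClass,
    SegmentedObject,
)

__all__ = [
    "read_image",
    "write_image",
    "write_label_map",
    "render_overlay",
    "objects_to_table",
    "features_to_table",
    "write_report",
    "load_config",
    "save_config",
]

REPORT_SCHEMA_VERSION = 1

# QC palette: cells blue, nuclei white, neuropil red
_CLASS_COLORS = {
    ObjectClass.CELL_BODY: (60, 120, 255),
    ObjectClass.NUCLEUS: (255, 255, 255),
    ObjectClass.NUCLEUS_CANDIDATE: (255, 255, 255),
    ObjectClass.NEUROPIL: (255, 60, 60),
    ObjectClass.GRANULE_OR_REJECTED: (160, 160, 60),
}


def read_image(path, pixel_size_um: float = 0.3, channel: str = "THG") -> IntensityImage:
    """Read an 8/16-bit grayscale TIFF into a [0, 1] intensity image."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # RGB(A): use luminance
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D grayscale image")
    arr = arr.astype(np.float64)
    if arr.max() > 1.0:
        arr = arr / np.iinfo(np.uint16).max if arr.max() > 255 else arr / 255.0
    return IntensityImage(np.clip(arr, 0, None), pixel_size_um=pixel_size_um,
                          channel=channel, provenance=str(path))


def write_image(path, img: IntensityImage) -> None:
    """Write a [0, 1] intensity image as 16-bit grayscale TIFF."""
    x = np.clip(img.pixels, 0.0, 1.0)
    tifffile.imwrite(str(path), (x * np.iinfo(np.uint16).max).astype(np.uint16))


def write_label_map(path, labels: np.ndarray) -> None:
    """Write an integer label raster as 8- or 16-bit TIFF."""
    labels = np.asarray(labels)
    dtype = np.uint8 if labels.max() < 256 else np.uint16
    tifffile.imwrite(str(path), labels.astype(dtype))


def render_overlay(
    img: IntensityImage, objects: list[SegmentedObject]
) -> np.ndarray:
    """Class-colored object contours over the grayscale image (uint8 RGB)."""
    base = np.clip(img.pixels, 0, 1)
    rgb = np.repeat((base * 255).astype(np.uint8)[..., None], 3, axis=2)
    shape = img.pixels.shape
    for obj in objects:
        color = _CLASS_COLORS.get(obj.object_class, (0, 255, 0))
        boundary = find_boundaries(obj.full_mask(shape), mode="inner")
        rgb[boundary] = color
    return rgb


def objects_to_table(objects: list[SegmentedObject]) -> pd.DataFrame:
    rows = [
        dict(id=o.id, object_class=o.object_class.value, area_px=o.area,
             perimeter_px=o.perimeter, sphericity=o.sphericity,
             centroid_row=o.centroid[0], centroid_col=o.centroid[1],
             phase_origin=o.phase_origin.value)
        for o in objects
    ]
    cols = ["id", "object_class", "area_px", "perimeter_px", "sphericity",
            "centroid_row", "centroid_col", "phase_origin"]
    return pd.DataFrame(rows, columns=cols)


def features_to_table(
    results: list[ClassificationResult] | list[FeatureRecord],
) -> pd.DataFrame:
    rows = []
    for r in results:
        f = r.features if isinstance(r, ClassificationResult) else r
        row = dict(image_id=f.image_id, tile_index=str(f.tile_index),
                   cell_pos=f.cell_pos, nucleus_pos=f.nucleus_pos,
                   neuropil_density=f.neuropil_density, n_cells=f.n_cells,
                   n_nuclei=f.n_nuclei, image_area_px=f.image_area_px)
        if isinstance(r, ClassificationResult):
            row["label"] = r.label.value
            row["triggered_rule"] = r.triggered_rule.value
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(path, results: list[ClassificationResult],
                 timestamp: str | None = None) -> None:
    """Write the JSON classification report (schema-versioned).

    ``timestamp`` is optional and off by default so that identical runs
    produce byte-identical reports.
    """
    payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "results": [
            {
                "image_id": r.features.image_id,
                "tile_index": list(r.features.tile_index)
                if r.features.tile_index else None,
                "label": r.label.value,
                "triggered_rule": r.triggered_rule.value,
                "cell_pos": r.features.cell_pos,
                "nucleus_pos": r.features.nucleus_pos,
                "neuropil_density": r.features.neuropil_density,
                "n_cells": r.features.n_cells,
                "n_nuclei": r.features.n_nuclei,
            }
            for r in results
        ],
    }
    if timestamp is not None:
        payload["timestamp"] = timestamp
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# -- configuration ---------------------------------------------------------

def _known_fields(cls) -> set[str]:
    return {f.name for f in dataclasses.fields(cls)}


def load_config(path, schema: dict) -> dict:
    """Load a sectioned YAML config, rejecting unknown sections/keys.

    ``schema`` maps section name -> parameter dataclass; returns section
    name -> instantiated dataclass (defaults where a section is absent).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(schema)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    out = {}
    for name, cls in schema.items():
        section = raw.get(name, {}) or {}
        bad = set(section) - _known_fields(cls)
        if bad:
            raise ValueError(f"unknown keys in [{name}]: {sorted(bad)}")
        coerced = {k: tuple(v) if isinstance(v, list) else v
                   for k, v in section.items()}
        hints = typing.get_type_hints(cls)
        for fname, value in list(coerced.items()):
            if isinstance(value, dict) and dataclasses.is_dataclass(hints.get(fname)):
                coerced[fname] = hints[fname](**value)
        out[name] = cls(**coerced)
    return out


def save_config(path, sections: dict) -> None:
    """Round-trippable YAML dump of parameter dataclasses."""
    payload = {}
    for name, obj in sections.items():
        d = dataclasses.asdict(obj)
        payload[name] = {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in d.items()}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
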