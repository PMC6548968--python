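"""Fixed-overlap mosaic stitching and tile cutting.

Adjacent microscope tiles are acquired with a fixed 20% overlap by stage
translation, so tile placement is known a priori: tiles are laid out at
(1 - overlap) * tile_shape spacing with linear feather blending inside
the overlap zones.  An optional cross-correlation refinement (small
search window) is available for real stage data with positioning error.
``cut_into_tiles`` is the exact inverse used for round-trip testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .datatypes import IntensityImage

__all__ = ["MosaicLayout", "stitch_mosaic", "cut_into_tiles"]


@dataclass(frozen=True)
class MosaicLayout:
    """Row-major tile grid with a fixed fractional overlap."""

    grid: tuple[int, int]
    overlap_fraction: float = 0.20

    def __post_init__(self) -> None:
        if min(self.grid) < 1:
            raise ValueError("grid must be at least 1x1")
        if not 0.0 <= self.overlap_fraction < 0.5:
            raise ValueError("overlap_fraction must lie in [0, 0.5)")


def _steps(n: int, tile: int, overlap: float) -> np.ndarray:
    step = int(round((1.0 - overlap) * tile))
    return np.arange(n) * step


def mosaic_shape(tile_shape: tuple[int, int], layout: MosaicLayout) -> tuple[int, int]:
    rows, cols = layout.grid
    th, tw = tile_shape
    oy = _steps(rows, th, layout.overlap_fraction)
    ox = _steps(cols, tw, layout.overlap_fraction)
    return int(oy[-1] + th), int(ox[-1] + tw)


def _feather_weight(tile_shape: tuple[int, int], overlap: float) -> np.ndarray:
    """Separable linear ramp over the overlap margin of a tile."""
    th, tw = tile_shape
    wy = np.ones(th)
    wx = np.ones(tw)
    my = int(round(overlap * th))
    mx = int(round(overlap * tw))
    if my > 0:
        ramp = np.linspace(1.0 / (my + 1), 1.0, my, endpoint=False)
        wy[:my] = ramp
        wy[-my:] = ramp[::-1]
    if mx > 0:
        ramp = np.linspace(1.0 / (mx + 1), 1.0, mx, endpoint=False)
        wx[:mx] = ramp
        wx[-mx:] = ramp[::-1]
    return np.outer(wy, wx)


def stitch_mosaic(
    tiles: list[IntensityImage],
    layout: MosaicLayout,
    refine: bool = False,
    refine_search_px: int = 5,
) -> IntensityImage:
    """Stitch row-major tiles into one mosaic image.

    Fixed-offset placement with linear feather blending in the overlap
    zones; weights are normalized, so a cut-and-restitch round trip
    reproduces the original to floating-point accuracy.  With
    ``refine=True`` each tile's nominal offset is adjusted by up to
    ``refine_search_px`` px via cross-correlation against the already
    blended canvas (for real stage data; off by default to keep the
    operation exactly deterministic with respect to layout alone).
    """
    rows, cols = layout.grid
    if len(tiles) != rows * cols:
        raise ValueError(f"expected {rows * cols} tiles, got {len(tiles)}")
    shapes = {t.pixels.shape for t in tiles}
    if len(shapes) != 1:
        raise ValueError("tiles must share one shape")
    tile_shape = tiles[0].pixels.shape
    H, W = mosaic_shape(tile_shape, layout)
    th, tw = tile_shape
    oy = _steps(rows, th, layout.overlap_fraction)
    ox = _steps(cols, tw, layout.overlap_fraction)
    weight = _feather_weight(tile_shape, layout.overlap_fraction)

    canvas = np.zeros((H, W))
    wsum = np.zeros((H, W))
    for idx, tile in enumerate(tiles):
        r, c = divmod(idx, cols)
        y0, x0 = int(oy[r]), int(ox[c])
        if refine and (r or c) and wsum.max() > 0:
            y0, x0 = _refine_offset(canvas, wsum, tile.pixels, y0, x0,
                                    refine_search_px)
        canvas[y0 : y0 + th, x0 : x0 + tw] += tile.pixels * weight
        wsum[y0 : y0 + th, x0 : x0 + tw] += weight
    out = np.where(wsum > 0, canvas / np.where(wsum > 0, wsum, 1.0), 0.0)
    return IntensityImage(np.clip(out, 0, None),
                          pixel_size_um=tiles[0].pixel_size_um,
                          channel=tiles[0].channel,
                          provenance=f"mosaic{layout.grid}")


def _refine_offset(canvas, wsum, tile, y0, x0, search):
    """Small exhaustive cross-correlation search around the nominal offset."""
    th, tw = tile.shape
    best = (y0, x0)
    best_score = -np.inf
    H, W = canvas.shape
    for dy in range(-search, search + 1):
        for dx in range(-search, search + 1):
            y, x = y0 + dy, x0 + dx
            if y < 0 or x < 0 or y + th > H or x + tw > W:
                continue
            w = wsum[y : y + th, x : x + tw]
            sel = w > 0
            if sel.sum() < 100:
                continue
            a = (canvas[y : y + th, x : x + tw][sel]
                 / w[sel])
            b = tile[sel]
            if a.std() == 0 or b.std() == 0:
                continue
            score = np.corrcoef(a, b)[0, 1]
            if score > best_score:
                best_score, best = score, (y, x)
    return best


def cut_into_tiles(
    img: IntensityImage, layout: MosaicLayout
) -> list[IntensityImage]:
    """Cut one image into an overlapping row-major tile grid.

    The inverse of :func:`stitch_mosaic` for exact fixed offsets; the
    image must be large enough for the requested grid, and the tile
    shape is derived from the image extent and the layout.
    """
    rows, cols = layout.grid
    H, W = img.pixels.shape
    ov = layout.overlap_fraction
    # H = th + (rows-1) * round((1-ov)*th): solve per axis
    th = _solve_tile_extent(H, rows, ov)
    tw = _solve_tile_extent(W, cols, ov)
    oy = _steps(rows, th, ov)
    ox = _steps(cols, tw, ov)
    tiles = []
    for r in range(rows):
        for c in range(cols):
            y0, x0 = int(oy[r]), int(ox[c])
            sub = img.pixels[y0 : y0 + th, x0 : x0 + tw]
            tiles.append(IntensityImage(sub.copy(),
                                        pixel_size_um=img.pixel_size_um,
                                        channel=img.channel,
                                        provenance=f"{img.provenance}/tile{r},{c}"))
    return tiles


def _solve_tile_extent(total: int, n: int, overlap: float) -> int:
    if n == 1:
        return total
    for th in range(total, 63, -1):
        if th + (n - 1) * int(round((1 - overlap) * th)) == total:
            return th
    raise ValueError(f"no integer tile extent tiles {total} px into {n} "
                     f"tiles at overlap {overlap}")
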