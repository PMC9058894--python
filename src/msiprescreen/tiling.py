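"""Slide tessellation and edge-quantity quality control.

Slides are cut into non-overlapping square tiles of fixed *physical* edge
length (default 256 um) and resampled to a fixed output edge (default
512 px), so that tiles from scanners with different resolutions are
comparable. Background and blurred tiles are then rejected by the mean of a
binary Canny edge map: tissue has abundant fine structure and scores high,
while glass background and out-of-focus regions score near zero.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from skimage import feature, transform

from .types import QCRecord, SlideRaster, Tile

__all__ = [
    "tessellate",
    "edge_sharpness_score",
    "qc_filter",
    "DEFAULT_TILE_EDGE_UM",
    "DEFAULT_OUT_EDGE_PX",
    "DEFAULT_QC_THRESHOLD",
]

DEFAULT_TILE_EDGE_UM = 256.0
DEFAULT_OUT_EDGE_PX = 512
DEFAULT_QC_THRESHOLD = 4.0

# Canny settings on the 0-255 grayscale: hysteresis (40, 100), smoothing
# sigma 1.4. The QC threshold of 4 operates on the mean of the {0, 255}
# edge map these settings produce.
CANNY_SIGMA = 1.4
CANNY_LOW = 40.0
CANNY_HIGH = 100.0

# BT.601 luminance weights (the convention of mainstream CV libraries).
_LUMA = np.array([0.299, 0.587, 0.114])


def tessellate(
    slide: SlideRaster,
    tile_edge_um: float = DEFAULT_TILE_EDGE_UM,
    out_edge_px: int = DEFAULT_OUT_EDGE_PX,
) -> list[Tile]:
    """Cut a slide into a row-major grid of non-overlapping tiles.

    The source-resolution footprint is ``round(tile_edge_um /
    microns_per_pixel)`` pixels; each footprint is resampled (bilinear) to
    ``out_edge_px``. Partial tiles at the right/bottom margins are dropped,
    so the result has exactly ``floor(H/src_edge) * floor(W/src_edge)``
    tiles.
    """
    mpp = slide.microns_per_pixel
    src_edge = int(round(tile_edge_um / mpp))
    if src_edge < 1:
        raise ValueError(
            f"tile footprint {tile_edge_um} um is below one pixel at {mpp} um/px"
        )
    H, W = slide.shape
    if src_edge > H or src_edge > W:
        warnings.warn(
            f"tile footprint {src_edge} px exceeds slide {H}x{W}; no tiles produced",
            stacklevel=2,
        )
        return []
    tiles: list[Tile] = []
    for y in range(0, H - src_edge + 1, src_edge):
        for x in range(0, W - src_edge + 1, src_edge):
            patch = slide.pixels[y : y + src_edge, x : x + src_edge]
            if src_edge != out_edge_px:
                out = transform.resize(
                    patch.astype(float),
                    (out_edge_px, out_edge_px),
                    order=1,
                    anti_aliasing=False,
                    preserve_range=True,
                )
                patch = np.clip(np.rint(out), 0, 255).astype(np.uint8)
            else:
                patch = patch.copy()
            tiles.append(
                Tile(
                    pixels=patch,
                    origin_x=x,
                    origin_y=y,
                    src_edge_px=src_edge,
                    edge_um=tile_edge_um,
                    slide_id=slide.slide_id,
                    patient_id=slide.patient_id,
                )
            )
    return tiles


def _grayscale(pixels: np.ndarray) -> np.ndarray:
    return pixels.astype(float) @ _LUMA


def edge_sharpness_score(tile: Tile) -> float:
    """Mean of the binary {0, 255} Canny edge map of the tile's grayscale.

    Constant (background) and heavily blurred tiles have no detectable
    edges and score 0; sharp tissue scores well above the removal
    threshold of 4.
    """
    gray = _grayscale(tile.pixels)
    if gray.max() == gray.min():
        return 0.0
    edges = feature.canny(
        gray, sigma=CANNY_SIGMA, low_threshold=CANNY_LOW, high_threshold=CANNY_HIGH
    )
    return float(edges.mean() * 255.0)


def qc_filter(
    tiles: Sequence[Tile], threshold: float = DEFAULT_QC_THRESHOLD
) -> tuple[list[Tile], list[QCRecord]]:
    """Keep tiles whose edge score is at or above ``threshold``.

    Removal is strictly "below the threshold": a tile scoring exactly the
    threshold is kept. Returns the kept tiles (input order preserved) and
    one QC record per input tile.
    """
    if threshold < 0:
        raise ValueError("QC threshold must be >= 0")
    records = []
    kept = []
    for tile in tiles:
        score = edge_sharpness_score(tile)
        passed = score >= threshold
        records.append(QCRecord(tile=tile, edge_score=score, passed=passed))
        if passed:
            kept.append(tile)
    return kept, records
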