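"""Tile-wise detection maps: prediction heatmaps over slide thumbnails.

The map grid is aligned to the tessellation grid: cell (i, j) shows the
MSI probability of the tile whose origin is (j * src_edge, i * src_edge).
Tiles removed by QC (or otherwise unscored) are rendered transparent, so
the map never implies a prediction where none was made. Rendering is pure
visualization — scores are never altered.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from matplotlib import colormaps
from matplotlib import pyplot as plt

from .types import SlideRaster, Tile, TileScore

__all__ = ["detection_grid", "render_map", "save_map"]


def detection_grid(
    slide: SlideRaster, tiles: Sequence[Tile], tile_scores: Sequence[TileScore]
) -> np.ndarray:
    """Per-tile probability grid aligned to the tessellation (NaN = no score)."""
    if not tiles:
        raise ValueError("no tiles to map")
    src = tiles[0].src_edge_px
    H, W = slide.shape
    n_rows, n_cols = H // src, W // src
    grid = np.full((n_rows, n_cols), np.nan)
    scored = {(ts.tile.origin_x, ts.tile.origin_y): ts.p_msi for ts in tile_scores}
    for tile in tiles:
        if tile.src_edge_px != src:
            raise ValueError("mixed tile footprints in one map")
        col, row = tile.origin_x // src, tile.origin_y // src
        if not (0 <= row < n_rows and 0 <= col < n_cols) or (
            tile.origin_x % src or tile.origin_y % src
        ):
            raise ValueError(
                f"tile at ({tile.origin_x}, {tile.origin_y}) is off the tessellation grid"
            )
        p = scored.get((tile.origin_x, tile.origin_y))
        if p is not None:
            grid[row, col] = p
    return grid


def render_map(
    slide: SlideRaster,
    tiles: Sequence[Tile],
    tile_scores: Sequence[TileScore],
    colormap: str = "coolwarm",
    opacity: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Blend the per-tile probability grid over the slide raster.

    The diverging colormap is centered at the tile threshold 0.5. Returns
    the composited uint8 RGB overlay (same size as the slide, up to the
    dropped margin) and the probability grid.
    """
    grid = detection_grid(slide, tiles, tile_scores)
    src = tiles[0].src_edge_px
    cmap = colormaps[colormap]
    colors = cmap(np.nan_to_num(grid, nan=0.0))[..., :3]  # rows x cols x 3 in [0,1]
    valid = ~np.isnan(grid)
    cell_rgb = np.kron(colors, np.ones((src, src, 1)))
    cell_alpha = np.kron(valid.astype(float) * opacity, np.ones((src, src)))
    Hc, Wc = grid.shape[0] * src, grid.shape[1] * src
    base = slide.pixels[:Hc, :Wc].astype(float) / 255.0
    out = base * (1.0 - cell_alpha[..., None]) + cell_rgb * cell_alpha[..., None]
    return (np.clip(np.rint(out * 255.0), 0, 255)).astype(np.uint8), grid


def save_map(
    path: str,
    slide: SlideRaster,
    tiles: Sequence[Tile],
    tile_scores: Sequence[TileScore],
    colormap: str = "coolwarm",
    opacity: float = 0.5,
    grid_csv: Optional[str] = None,
) -> None:
    """Write the overlay PNG with a probability legend bar (and sidecar CSV)."""
    overlay, grid = render_map(slide, tiles, tile_scores, colormap, opacity)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(overlay)
    ax.set_axis_off()
    sm = plt.cm.ScalarMappable(cmap=colormaps[colormap], norm=plt.Normalize(0, 1))
    fig.colorbar(sm, ax=ax, fraction=0.046, label="tile-level P(MSI)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    if grid_csv is not None:
        np.savetxt(grid_csv, grid, delimiter=",", fmt="%.6f")
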