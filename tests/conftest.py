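import numpy as np
import pytest

from msiprescreen import synth, tiling
from msiprescreen.types import Tile


def _texture_tiles(primitive: str, n_min: int, seed: int) -> list[Tile]:
    """QC-passing tiles of one texture class, rendered at desk resolution."""
    rng = np.random.default_rng(seed)
    tiles: list[Tile] = []
    while len(tiles) < n_min:
        if primitive == "discs":
            spec = synth.TextureSpec(label=1, primitive="discs", radius_range=(3.0, 6.0))
        else:
            spec = synth.TextureSpec(
                label=0, primitive="rings", radius_range=(8.0, 14.0), density=25.0
            )
        slide = synth.make_synthetic_slide(
            spec, size_px=640, seed=int(rng.integers(2**31))
        )
        kept, _ = tiling.qc_filter(tiling.tessellate(slide, out_edge_px=128))
        tiles.extend(kept)
    return tiles


@pytest.fixture(scope="session")
def disc_tiles() -> list[Tile]:
    """MSI-like texture (dense small filled discs), >= 220 tiles."""
    return _texture_tiles("discs", 220, seed=101)


@pytest.fixture(scope="session")
def ring_tiles() -> list[Tile]:
    """MSS-like texture (gland-like rings), >= 220 tiles."""
    return _texture_tiles("rings", 220, seed=202)


@pytest.fixture()
def constant_tile() -> Tile:
    return Tile(
        pixels=np.full((128, 128, 3), 200, dtype=np.uint8),
        origin_x=0,
        origin_y=0,
        src_edge_px=128,
        edge_um=256.0,
    )


def make_checkerboard_tile(block: int = 8, edge: int = 512) -> Tile:
    cb = ((np.indices((edge, edge)).sum(axis=0) // block) % 2 * 255).astype(np.uint8)
    return Tile(
        pixels=np.repeat(cb[:, :, None], 3, axis=2),
        origin_x=0,
        origin_y=0,
        src_edge_px=edge,
        edge_um=256.0,
    )
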