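"""End-to-end wiring: slides -> tiles -> QC -> normalization -> scorer ->
patient scores.

This module provides the ``score_fn`` used by the study designs: given
train and test patient records (with in-memory slides or slide paths), it
tessellates, QC-filters, Macenko-normalizes and caps tiles, trains the
configured scorer on class-balanced training tiles, and aggregates
tile probabilities into one score per test patient.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import aggregate, scoring, stain, tiling
from .types import DegenerateStainError, PatientScore, SlideRaster, StainContext, Tile

__all__ = ["PipelineConfig", "default_target_context", "make_pipeline_score_fn",
           "patient_tiles"]


@dataclass
class PipelineConfig:
    """Configuration of the tile-to-score pipeline."""

    tile_edge_um: float = tiling.DEFAULT_TILE_EDGE_UM
    out_edge_px: int = tiling.DEFAULT_OUT_EDGE_PX
    qc_threshold: float = tiling.DEFAULT_QC_THRESHOLD
    normalize: bool = True
    target_context: Optional[StainContext] = None
    tile_cap: int = 500
    tile_threshold: float = aggregate.DEFAULT_TILE_THRESHOLD
    backbone: str = "small_cnn"
    scorer_config: scoring.ScorerConfig = field(
        default_factory=lambda: scoring.ScorerConfig.desk_scale(epochs=10)
    )

    def resolved_target(self) -> Optional[StainContext]:
        if not self.normalize:
            return None
        if self.target_context is None:
            self.target_context = default_target_context()
        return self.target_context


def default_target_context(seed: int = 20_2206) -> StainContext:
    """Stain context of the built-in synthetic normalization target.

    A fixed-seed Beer-Lambert rendering with the classic H&E stain vectors
    serves as the default target image; any PNG can be supplied instead
    through the run configuration.
    """
    from .synth import HE_STAIN_MATRIX

    rng = np.random.default_rng(seed)
    conc = rng.uniform(0.0, 1.5, size=(2, 40_000))
    od = (HE_STAIN_MATRIX @ conc).T.reshape(200, 200, 3)
    return stain.estimate_stain_matrix(stain.od_to_rgb(od))


def _patient_rng(seed: int, patient_id: str) -> np.random.Generator:
    # Stable per-patient stream: tile sampling does not depend on the
    # order in which patients are processed.
    return np.random.default_rng([seed, zlib.crc32(patient_id.encode())])


def _slides_of(patient) -> list[SlideRaster]:
    if patient.slides:
        return patient.slides
    from .manifest import load_slide

    mpp = getattr(patient, "manifest_mpp", None)  # manifest wins over image tags
    return [
        load_slide(p, microns_per_pixel=mpp, patient_id=patient.patient_id)
        for p in patient.slide_paths
    ]


def patient_tiles(
    patient, config: PipelineConfig, seed: int = 0
) -> list[Tile]:
    """All QC-passing (optionally normalized) tiles of one patient, capped.

    Tiles are pooled across the patient's slides before the 500-tile cap
    is applied. Slides whose stain matrix cannot be estimated (blank or
    single-dye) pass through unnormalized with a warning.
    """
    target = config.resolved_target()
    kept_all: list[Tile] = []
    for slide in _slides_of(patient):
        tiles = tiling.tessellate(slide, config.tile_edge_um, config.out_edge_px)
        kept, _ = tiling.qc_filter(tiles, config.qc_threshold)
        if target is not None and kept:
            try:
                src = stain.estimate_stain_matrix(slide.pixels)
                kept = [stain.macenko_normalize(t, src, target) for t in kept]
            except DegenerateStainError:
                warnings.warn(
                    f"slide {slide.slide_id!r}: degenerate stains, not normalized",
                    stacklevel=2,
                )
        kept_all.extend(kept)
    return scoring.sample_patient_tiles(
        kept_all, cap=config.tile_cap, rng=_patient_rng(seed, patient.patient_id)
    )


def make_pipeline_score_fn(config: PipelineConfig):
    """Build the (train, test, seed) -> patient scores function for a design.

    Training tiles are class-balanced by undersampling; test tiles never
    are. Patients whose tiles are all removed by QC are excluded from the
    output with a warning (unevaluable).
    """

    # Tiling/QC/normalization of a patient is fold-independent, so tiles
    # are computed once per (patient, seed) and reused across folds.
    cache: dict[tuple[str, int], list[Tile]] = {}

    def _tiles(p, seed: int) -> list[Tile]:
        key = (p.patient_id, seed)
        if key not in cache:
            cache[key] = patient_tiles(p, config, seed)
        return cache[key]

    def score_fn(train_patients: Sequence, test_patients: Sequence, seed: int):
        tiles0: list[Tile] = []
        tiles1: list[Tile] = []
        for p in train_patients:
            tl = _tiles(p, seed)
            (tiles1 if p.label == 1 else tiles0).extend(tl)
        balanced, labels = scoring.balance_training_tiles(
            tiles0, tiles1, rng=np.random.default_rng([seed, 0xBA1A])
        )
        cfg = scoring.ScorerConfig(**{**vars(config.scorer_config), "seed": seed})
        scorer = scoring.train_tile_scorer(balanced, labels, cfg, config.backbone)

        results: list[PatientScore] = []
        for p in test_patients:
            tl = _tiles(p, seed)
            if not tl:
                warnings.warn(
                    f"patient {p.patient_id!r}: no tiles passed QC; unevaluable",
                    stacklevel=2,
                )
                continue
            tile_scores = scoring.score_tiles(scorer, tl)
            results.append(
                aggregate.aggregate_patient(
                    tile_scores,
                    tile_threshold=config.tile_threshold,
                    patient_id=p.patient_id,
                    cohort_id=p.cohort_id,
                    label=p.label,
                )
            )
        return results

    return score_fn
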