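"""Patient-level aggregation of tile probabilities.

A patient's score is the fraction of their tiles whose MSI probability
exceeds the tile-level threshold (default 0.5, strictly greater), pooled
across all of the patient's slides. The score is therefore a count
fraction in [0, 1] and directly comparable across patients with different
tile counts.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .types import PatientScore, TileScore

__all__ = ["aggregate_patient", "DEFAULT_TILE_THRESHOLD"]

DEFAULT_TILE_THRESHOLD = 0.5


def aggregate_patient(
    tile_scores: Sequence[TileScore],
    tile_threshold: float = DEFAULT_TILE_THRESHOLD,
    patient_id: str = "",
    cohort_id: str = "",
    label: Optional[int] = None,
) -> PatientScore:
    """Fraction of tiles with ``p_msi > tile_threshold``.

    The comparison is strictly greater, so a tile sitting exactly at the
    threshold does not count as MSI-predicted. Raises ``ValueError`` on an
    empty tile list (a patient whose tiles were all removed by QC is
    unevaluable and must be excluded upstream, with the reason logged).
    """
    n = len(tile_scores)
    if n == 0:
        raise ValueError(
            f"patient {patient_id!r} has no scored tiles (all removed by QC?); "
            "unevaluable"
        )
    positive = sum(1 for ts in tile_scores if ts.p_msi > tile_threshold)
    return PatientScore(
        patient_id=patient_id,
        score=positive / n,
        n_tiles=n,
        cohort_id=cohort_id,
        label=label,
    )
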