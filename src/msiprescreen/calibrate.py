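"""Threshold calibration: the three strategies for turning patient scores
into rule-in/rule-out decisions.

* cohort-specific — the largest threshold that keeps sensitivity at or
  above a fixed target (default 95%) on the cohort itself;
* fixed — global candidate thresholds (0.25, 0.50, 0.75) applied to every
  cohort unchanged;
* learned — the unweighted mean of per-training-cohort optima, each
  obtained from pooled out-of-fold scores of a patient-level
  cross-validation within that cohort.

The prediction rule everywhere is "MSI if score >= threshold", so a
threshold equal to a positive patient's score counts that patient as
detected.
"""

from __future__ import annotations

import math
import warnings
from typing import Callable, Optional, Sequence

import numpy as np

from .designs import stratified_folds
from .types import CalibrationError, Cohort, PatientScore, ThresholdPolicy

__all__ = [
    "threshold_at_sensitivity",
    "fixed_policies",
    "learned_threshold",
    "sensitivity_at",
    "DEFAULT_TARGET_SENSITIVITY",
    "DEFAULT_FIXED_VALUES",
]

DEFAULT_TARGET_SENSITIVITY = 0.95
DEFAULT_FIXED_VALUES = (0.25, 0.50, 0.75)


def sensitivity_at(scores: Sequence[PatientScore], value: float) -> float:
    """Sensitivity of the rule "MSI if score >= value" on labeled scores."""
    pos = [p.score for p in scores if p.label == 1]
    if not pos:
        raise CalibrationError("no positive-labeled patients")
    return float(np.mean(np.asarray(pos) >= value))


def threshold_at_sensitivity(
    scores: Sequence[PatientScore],
    target: float = DEFAULT_TARGET_SENSITIVITY,
    kind: str = "cohort_specific",
) -> ThresholdPolicy:
    """Largest threshold whose calibration-set sensitivity is >= target.

    With n positive patients this is the k-th largest positive score,
    k = ceil(target * n): every larger candidate detects fewer than k
    positives. The achieved sensitivity on the calibration set is by
    construction >= target.
    """
    if not 0.0 < target <= 1.0:
        raise ValueError("target sensitivity must be in (0, 1]")
    pos = np.sort([p.score for p in scores if p.label == 1])[::-1]
    if pos.size == 0:
        raise CalibrationError("cannot calibrate a threshold without positives")
    k = math.ceil(target * pos.size)
    value = float(pos[k - 1])
    return ThresholdPolicy(
        kind=kind,
        value=value,
        target_sensitivity=target,
        provenance={
            "n_positives": int(pos.size),
            "achieved_sensitivity": float(np.mean(pos >= value)),
        },
    )


def fixed_policies(
    values: Sequence[float] = DEFAULT_FIXED_VALUES,
) -> list[ThresholdPolicy]:
    """Cohort-independent global threshold candidates (default 0.25/0.50/0.75)."""
    return [ThresholdPolicy(kind="fixed", value=float(v)) for v in values]


def learned_threshold(
    cohorts: Sequence[Cohort | Sequence[PatientScore]],
    folds: int = 3,
    target: float = DEFAULT_TARGET_SENSITIVITY,
    seed: int = 0,
    rescore: Optional[Callable] = None,
) -> ThresholdPolicy:
    """Average the per-cohort fixed-sensitivity optima over training cohorts.

    For each cohort, label-stratified patient-level k-fold CV yields one
    out-of-fold score per patient; the cohort's optimum is the
    fixed-sensitivity threshold on the pooled out-of-fold scores, and the
    learned value is the unweighted mean of the optima. ``rescore(train,
    test, seed) -> list[PatientScore]`` re-scores each test fold with a
    model fitted on the train folds; without it the stored scores are used
    as-is (correct for any scorer that is independent of the fold split).

    Cohorts too small to stratify are skipped with a warning; calibration
    fails only if no cohort is usable.
    """
    optima: dict[str, float] = {}
    for ci, cohort in enumerate(cohorts):
        scores = list(cohort.patients) if isinstance(cohort, Cohort) else list(cohort)
        cid = cohort.cohort_id if isinstance(cohort, Cohort) else f"cohort{ci}"
        labels = np.array([p.label for p in scores])
        if (labels == 1).sum() < folds or (labels == 0).sum() < folds:
            warnings.warn(
                f"cohort {cid!r} too small to stratify into {folds} folds; skipped",
                stacklevel=2,
            )
            continue
        oof: list[PatientScore] = []
        for train_idx, test_idx in stratified_folds(labels, folds, seed=seed):
            if rescore is None:
                oof.extend(scores[i] for i in test_idx)
            else:
                oof.extend(
                    rescore([scores[i] for i in train_idx],
                            [scores[i] for i in test_idx], seed)
                )
        optima[cid] = threshold_at_sensitivity(oof, target=target).value
    if not optima:
        raise CalibrationError("no cohort was usable for learned-threshold calibration")
    value = float(np.mean(list(optima.values())))
    return ThresholdPolicy(
        kind="learned",
        value=value,
        target_sensitivity=target,
        provenance={"per_cohort_optima": optima, "folds": folds, "seed": seed},
    )
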