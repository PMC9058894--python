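"""Study designs: leave-one-cohort-out validation and within-cohort CV.

Leave-one-cohort-out (LOCO) trains one model per held-out cohort on the
patients of all other cohorts and scores every held-out patient with a
model that never saw them; within-cohort cross-validation splits a single
cohort into label-stratified patient-level folds and scores each patient
out-of-fold exactly once. Patient disjointness between train and test is
asserted on every fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .types import Cohort, MetricCI, PatientScore, ThresholdPolicy, UndefinedMetricError

__all__ = [
    "stratified_folds",
    "within_cohort_cv",
    "leave_one_cohort_out",
    "CohortResult",
]

# score_fn(train_patients, test_patients, seed) -> list[PatientScore] for test
ScoreFn = Callable[[Sequence, Sequence, int], list[PatientScore]]


@dataclass
class CohortResult:
    """Evaluation of one held-out cohort under all threshold policies."""

    cohort_id: str
    scores: list  # list[PatientScore]
    auroc: Optional[float]
    auroc_ci: Optional[MetricCI]
    policies: dict = field(default_factory=dict)  # name -> ThresholdPolicy
    confusion: dict = field(default_factory=dict)  # name -> ConfusionStats

    @property
    def n(self) -> int:
        return len(self.scores)


def stratified_folds(
    labels: Sequence[int], k: int, seed: int = 0, stratified: bool = True
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Patient-level k-fold split indices, label-stratified by default."""
    labels = np.asarray(labels)
    if len(labels) < k:
        raise ValueError(f"cannot split {len(labels)} patients into {k} folds")
    if stratified:
        if (labels == 1).sum() < k or (labels == 0).sum() < k:
            raise ValueError(
                f"need at least {k} patients of each class for stratified {k}-fold"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(len(labels)), labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(len(labels)))
    folds = []
    for train_idx, test_idx in split:
        assert len(np.intersect1d(train_idx, test_idx)) == 0
        folds.append((train_idx, test_idx))
    return folds


def _assert_disjoint(train_patients, test_patients) -> None:
    train_ids = {p.patient_id for p in train_patients}
    test_ids = {p.patient_id for p in test_patients}
    overlap = train_ids & test_ids
    if overlap:
        raise AssertionError(f"patient leakage between train and test: {overlap}")


def within_cohort_cv(
    cohort: Cohort,
    score_fn: ScoreFn,
    folds: int = 3,
    seed: int = 0,
    stratified: bool = True,
) -> list[PatientScore]:
    """Out-of-fold patient scores from k-fold CV inside one cohort.

    Every patient is scored exactly once, by a model fitted on the other
    folds. Multi-slide patients travel as a unit (splitting is by patient).
    """
    patients = cohort.patients
    labels = [p.label for p in patients]
    oof: dict[str, PatientScore] = {}
    for train_idx, test_idx in stratified_folds(labels, folds, seed, stratified):
        train = [patients[i] for i in train_idx]
        test = [patients[i] for i in test_idx]
        _assert_disjoint(train, test)
        for ps in score_fn(train, test, seed):
            if ps.patient_id in oof:
                raise AssertionError(f"patient {ps.patient_id} scored twice")
            oof[ps.patient_id] = ps
    missing = {p.patient_id for p in patients} - set(oof)
    if missing:
        raise AssertionError(f"patients never scored out-of-fold: {missing}")
    return [oof[p.patient_id] for p in patients]


def leave_one_cohort_out(
    cohorts: Sequence[Cohort],
    score_fn: ScoreFn,
    seed: int = 0,
    target_sensitivity: float = 0.95,
    fixed_values: Sequence[float] = (0.25, 0.50, 0.75),
    learned_folds: int = 3,
    n_boot: int = 1000,
    ci_level: float = 0.95,
) -> list[CohortResult]:
    """Run the full leave-one-cohort-out design.

    For each held-out cohort: fit on all other cohorts' patients via
    ``score_fn``, score the held-out patients, then evaluate three policy
    families — the cohort-specific fixed-sensitivity threshold (calibrated
    on the held-out scores), the global fixed thresholds, and the learned
    threshold averaged over the training cohorts' out-of-fold optima (the
    held-out cohort never contributes to its own learned threshold).
    Cohorts with a single class are evaluated for confusion statistics
    only, with AUROC marked undefined.
    """
    from . import calibrate, metrics

    if len(cohorts) < 2:
        raise ValueError("leave-one-cohort-out requires at least 2 cohorts")
    all_ids = [p.patient_id for c in cohorts for p in c.patients]
    if len(all_ids) != len(set(all_ids)):
        raise ValueError("patient ids must be unique across cohorts")

    # Each cohort's within-cohort CV optimum is independent of which cohort
    # is held out, so the CV models are fitted once per cohort and the
    # learned threshold for a fold averages the training cohorts' optima.
    cohort_optima: dict[str, float] = {}
    for c in cohorts:
        cl = np.array([p.label for p in c.patients])
        if (cl == 1).sum() < learned_folds or (cl == 0).sum() < learned_folds:
            continue
        oof = within_cohort_cv(c, score_fn, learned_folds, seed)
        cohort_optima[c.cohort_id] = calibrate.threshold_at_sensitivity(
            oof, target=target_sensitivity
        ).value

    results: list[CohortResult] = []
    for held_out in cohorts:
        train_cohorts = [c for c in cohorts if c.cohort_id != held_out.cohort_id]
        train_patients = [p for c in train_cohorts for p in c.patients]
        _assert_disjoint(train_patients, held_out.patients)
        scores = score_fn(train_patients, held_out.patients, seed)

        labels = np.array([s.label for s in scores])
        single_class = (labels == 1).all() or (labels == 0).all()
        if single_class:
            auc, ci = None, None
        else:
            auc = metrics.auroc(scores)
            ci = metrics.bootstrap_ci(
                scores,
                None,
                metrics.auroc,
                n_boot=n_boot,
                level=ci_level,
                rng=np.random.default_rng(seed),
            )

        policies: dict[str, ThresholdPolicy] = {}
        if (labels == 1).any():
            policies["cohort_specific"] = calibrate.threshold_at_sensitivity(
                scores, target=target_sensitivity
            )
        for pol in calibrate.fixed_policies(fixed_values):
            policies[f"fixed_{pol.value:g}"] = pol
        # Learned threshold from the training cohorts only (the held-out
        # cohort never contributes to its own learned threshold).
        optima = {
            cid: v
            for cid, v in cohort_optima.items()
            if cid != held_out.cohort_id
        }
        if optima:
            policies["learned"] = ThresholdPolicy(
                kind="learned",
                value=float(np.mean(list(optima.values()))),
                target_sensitivity=target_sensitivity,
                provenance={"per_cohort_optima": optima, "folds": learned_folds},
            )

        confusion = {
            name: metrics.confusion_at(scores, policy=pol)
            for name, pol in policies.items()
        }
        results.append(
            CohortResult(
                cohort_id=held_out.cohort_id,
                scores=scores,
                auroc=auc,
                auroc_ci=ci,
                policies=policies,
                confusion=confusion,
            )
        )
    # Partition check: every patient tested exactly once across folds.
    tested = [s.patient_id for r in results for s in r.scores]
    assert len(tested) == len(set(tested))
    return results
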