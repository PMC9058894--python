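"""Leave-one-cohort-out and within-cohort cross-validation designs."""

import zlib

import numpy as np
import pytest

from msiprescreen import designs, metrics
from msiprescreen.types import Cohort, PatientRecord, PatientScore


def _cohort(cid, n, n_pos, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    rng.shuffle(labels)
    return Cohort(
        cohort_id=cid,
        patients=[
            PatientRecord(patient_id=f"{cid}_p{i}", cohort_id=cid, label=int(l))
            for i, l in enumerate(labels)
        ],
    )


def _hash_score(pid: str) -> float:
    return (zlib.crc32(pid.encode()) % 1000) / 999.0


def data_independent_score_fn(train, test, seed):
    """Mock scorer: the score depends only on the patient id, never on train."""
    return [
        PatientScore(patient_id=p.patient_id, score=_hash_score(p.patient_id),
                     n_tiles=10, cohort_id=p.cohort_id, label=p.label)
        for p in test
    ]


class TestStratifiedFolds:
    def test_equal_fold_sizes(self):
        folds = designs.stratified_folds([0] * 21 + [1] * 9, 3, seed=0)
        sizes = sorted(len(test) for _, test in folds)
        assert sizes == [10, 10, 10]

    def test_every_patient_in_exactly_one_test_fold(self):
        labels = [0] * 20 + [1] * 10
        folds = designs.stratified_folds(labels, 3, seed=1)
        tested = np.concatenate([test for _, test in folds])
        assert sorted(tested) == list(range(30))

    @pytest.mark.parametrize("seed", range(5))
    def test_fold_prevalence_close_to_cohort(self, seed):
        labels = np.array([1] * 10 + [0] * 20)
        for _, test in designs.stratified_folds(labels, 3, seed=seed):
            n_pos = labels[test].sum()
            assert abs(n_pos - 10 / 3) <= 1

    def test_too_few_positives_error(self):
        with pytest.raises(ValueError, match="each class"):
            designs.stratified_folds([0] * 10 + [1], 3)

    def test_unstratified_variant(self):
        folds = designs.stratified_folds([0] * 10 + [1], 3, stratified=False)
        assert len(folds) == 3


class TestWithinCohortCV:
    def test_every_patient_scored_once(self):
        cohort = _cohort("a", 30, 9)
        oof = designs.within_cohort_cv(cohort, data_independent_score_fn, folds=3)
        assert sorted(p.patient_id for p in oof) == sorted(
            p.patient_id for p in cohort.patients
        )

    def test_out_of_fold_models_count(self):
        calls = []

        def counting_fn(train, test, seed):
            calls.append(len(train))
            return data_independent_score_fn(train, test, seed)

        designs.within_cohort_cv(_cohort("a", 30, 9), counting_fn, folds=3)
        assert len(calls) == 3


class TestLeaveOneCohortOut:
    def _study(self, k=4):
        return [_cohort(f"c{i}", 20, 6, seed=i) for i in range(k)]

    def test_one_result_per_cohort_all_patients_once(self):
        cohorts = self._study()
        results = designs.leave_one_cohort_out(
            cohorts, data_independent_score_fn, n_boot=50
        )
        assert [r.cohort_id for r in results] == [c.cohort_id for c in cohorts]
        tested = [s.patient_id for r in results for s in r.scores]
        assert sorted(tested) == sorted(p.patient_id for c in cohorts for p in c.patients)

    def test_auroc_matches_direct_computation(self):
        # with a data-independent scorer, orchestration must reproduce the
        # directly computed per-cohort AUROC
        cohorts = self._study()
        results = designs.leave_one_cohort_out(
            cohorts, data_independent_score_fn, n_boot=50
        )
        for r, cohort in zip(results, cohorts):
            direct = metrics.auroc(
                [_hash_score(p.patient_id) for p in cohort.patients],
                [p.label for p in cohort.patients],
            )
            assert r.auroc == pytest.approx(direct)

    def test_trains_one_main_model_per_cohort(self):
        # cohorts too small for within-cohort CV: exactly k score_fn calls
        cohorts = [_cohort(f"c{i}", 6, 2, seed=i) for i in range(3)]
        calls = []

        def counting_fn(train, test, seed):
            calls.append((len(train), len(test)))
            return data_independent_score_fn(train, test, seed)

        results = designs.leave_one_cohort_out(cohorts, counting_fn, n_boot=50)
        assert len(calls) == 3
        assert all("learned" not in r.policies for r in results)

    def test_learned_policy_excludes_held_out_cohort(self):
        results = designs.leave_one_cohort_out(
            self._study(), data_independent_score_fn, n_boot=50
        )
        for r in results:
            optima = r.policies["learned"].provenance["per_cohort_optima"]
            assert r.cohort_id not in optima
            assert len(optima) == 3

    def test_policies_present_with_confusion(self):
        results = designs.leave_one_cohort_out(
            self._study(), data_independent_score_fn, n_boot=50
        )
        for r in results:
            for name in ("cohort_specific", "fixed_0.25", "fixed_0.5", "fixed_0.75",
                         "learned"):
                assert name in r.policies and name in r.confusion
                assert r.confusion[name].n == r.n

    def test_single_class_cohort_auroc_undefined(self):
        cohorts = [_cohort("c0", 10, 0), _cohort("c1", 20, 6)]
        results = designs.leave_one_cohort_out(
            cohorts, data_independent_score_fn, n_boot=50
        )
        r0 = results[0]
        assert r0.auroc is None
        assert "cohort_specific" not in r0.policies  # no positives to calibrate on
        assert r0.confusion["fixed_0.5"].n == 10

    def test_duplicate_patient_ids_rejected(self):
        c0 = _cohort("c0", 10, 3)
        c1 = _cohort("c0", 10, 3)  # same ids
        c1.cohort_id = "c1"
        for p in c1.patients:
            p.cohort_id = "c1"
        with pytest.raises(ValueError, match="unique"):
            designs.leave_one_cohort_out([c0, c1], data_independent_score_fn)

    def test_two_cohorts_minimum(self):
        with pytest.raises(ValueError):
            designs.leave_one_cohort_out([_cohort("a", 10, 3)], data_independent_score_fn)

    def test_reproducible(self):
        a = designs.leave_one_cohort_out(self._study(), data_independent_score_fn,
                                         seed=5, n_boot=50)
        b = designs.leave_one_cohort_out(self._study(), data_independent_score_fn,
                                         seed=5, n_boot=50)
        assert [(s.patient_id, s.score) for r in a for s in r.scores] == [
            (s.patient_id, s.score) for r in b for s in r.scores
        ]
        assert [r.auroc_ci.lower for r in a] == [r.auroc_ci.lower for r in b]
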