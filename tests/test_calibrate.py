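"""Threshold calibration strategies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msiprescreen import calibrate
from msiprescreen.types import CalibrationError, Cohort, PatientScore


def _cohort(pos_scores, neg_scores=(), cohort_id="c"):
    scores = [
        PatientScore(patient_id=f"{cohort_id}_pos{i}", score=s, n_tiles=100,
                     cohort_id=cohort_id, label=1)
        for i, s in enumerate(pos_scores)
    ] + [
        PatientScore(patient_id=f"{cohort_id}_neg{i}", score=s, n_tiles=100,
                     cohort_id=cohort_id, label=0)
        for i, s in enumerate(neg_scores)
    ]
    return scores


def _scan_oracle(scores, target):
    """Exhaustive scan over all distinct scores for the maximal threshold."""
    pos = np.array([p.score for p in scores if p.label == 1])
    candidates = sorted({p.score for p in scores}, reverse=True)
    best = None
    for t in candidates:
        if (pos >= t).mean() >= target:
            return t
    return best


class TestThresholdAtSensitivity:
    def test_worked_example(self):
        scores = _cohort([0.9, 0.7, 0.5, 0.3, 0.2])
        policy = calibrate.threshold_at_sensitivity(scores, target=0.8)
        assert policy.value == 0.3
        assert policy.provenance["achieved_sensitivity"] == pytest.approx(0.8)
        assert policy.value == _scan_oracle(scores, 0.8)

    def test_full_sensitivity_is_min_positive(self):
        scores = _cohort([0.9, 0.7, 0.5, 0.3, 0.2])
        assert calibrate.threshold_at_sensitivity(scores, target=1.0).value == 0.2

    def test_single_positive(self):
        scores = _cohort([0.6], neg_scores=[0.1, 0.2])
        for target in (0.5, 0.95, 1.0):
            assert calibrate.threshold_at_sensitivity(scores, target=target).value == 0.6

    def test_no_positives_error(self):
        with pytest.raises(CalibrationError):
            calibrate.threshold_at_sensitivity(_cohort([], [0.1, 0.2]))

    def test_tied_positive_scores(self):
        scores = _cohort([0.4, 0.4, 0.4])
        assert calibrate.threshold_at_sensitivity(scores).value == 0.4

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(st.integers(0, 100), min_size=1, max_size=40),
        st.lists(st.integers(0, 100), max_size=40),
        st.floats(0.05, 1.0),
    )
    def test_matches_exhaustive_scan_and_is_maximal(self, pos, neg, target):
        scores = _cohort([p / 100 for p in pos], [n / 100 for n in neg])
        policy = calibrate.threshold_at_sensitivity(scores, target=target)
        assert calibrate.sensitivity_at(scores, policy.value) >= target
        assert policy.value == _scan_oracle(scores, target)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 100), min_size=2, max_size=40))
    def test_monotone_nonincreasing_in_target(self, pos):
        scores = _cohort([p / 100 for p in pos])
        values = [
            calibrate.threshold_at_sensitivity(scores, target=t).value
            for t in (0.5, 0.8, 0.9, 0.95, 1.0)
        ]
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestFixedPolicies:
    def test_default_values(self):
        policies = calibrate.fixed_policies()
        assert [p.value for p in policies] == [0.25, 0.50, 0.75]
        assert all(p.kind == "fixed" for p in policies)

    def test_override(self):
        [p] = calibrate.fixed_policies([0.3])
        assert p.value == 0.3


class TestLearnedThreshold:
    def _cohort_with_optimum(self, cid, opt, n_pos=6, n_neg=6):
        # all positives share one score => the cohort optimum equals it
        return Cohort(
            cohort_id=cid,
            patients=_cohort([opt] * n_pos, [opt / 2] * n_neg, cohort_id=cid),
        )

    def test_unweighted_mean(self):
        policy = calibrate.learned_threshold(
            [self._cohort_with_optimum("a", 0.2), self._cohort_with_optimum("b", 0.4)]
        )
        assert policy.value == pytest.approx(0.3)
        assert policy.provenance["per_cohort_optima"] == {"a": 0.2, "b": 0.4}

    def test_single_cohort_is_own_optimum(self):
        policy = calibrate.learned_threshold([self._cohort_with_optimum("a", 0.35)])
        assert policy.value == pytest.approx(0.35)

    def test_within_range_of_optima(self):
        rng = np.random.default_rng(0)
        cohorts = [
            Cohort(cohort_id=f"c{i}",
                   patients=_cohort(rng.uniform(0.3, 1.0, 20).tolist(),
                                    rng.uniform(0.0, 0.6, 60).tolist(),
                                    cohort_id=f"c{i}"))
            for i in range(4)
        ]
        policy = calibrate.learned_threshold(cohorts)
        optima = list(policy.provenance["per_cohort_optima"].values())
        assert min(optima) <= policy.value <= max(optima)

    def test_homogeneous_cohorts_agree(self):
        # cohorts drawn from one score distribution: the learned value stays
        # within +/-0.05 of each cohort's own optimum
        for seed in range(5):
            rng = np.random.default_rng(seed)
            cohorts = [
                Cohort(cohort_id=f"c{i}",
                       patients=_cohort(rng.beta(8, 2, 300).tolist(),
                                        rng.beta(2, 8, 400).tolist(),
                                        cohort_id=f"c{i}"))
                for i in range(8)
            ]
            policy = calibrate.learned_threshold(cohorts, seed=seed)
            for opt in policy.provenance["per_cohort_optima"].values():
                assert abs(policy.value - opt) <= 0.05

    def test_small_cohort_skipped_with_warning(self):
        good = self._cohort_with_optimum("big", 0.4)
        tiny = Cohort(cohort_id="tiny", patients=_cohort([0.9], [0.1], cohort_id="tiny"))
        with pytest.warns(UserWarning, match="tiny"):
            policy = calibrate.learned_threshold([good, tiny])
        assert policy.provenance["per_cohort_optima"] == {"big": 0.4}

    def test_no_usable_cohort_error(self):
        tiny = Cohort(cohort_id="tiny", patients=_cohort([0.9], [0.1], cohort_id="tiny"))
        with pytest.warns(UserWarning):
            with pytest.raises(CalibrationError):
                calibrate.learned_threshold([tiny])

    def test_rescore_callback_used(self):
        cohort = self._cohort_with_optimum("a", 0.4)

        def rescore(train, test, seed):
            return [
                PatientScore(patient_id=p.patient_id, score=0.8, n_tiles=10,
                             cohort_id=p.cohort_id, label=p.label)
                for p in test
            ]

        policy = calibrate.learned_threshold([cohort], rescore=rescore)
        assert policy.value == pytest.approx(0.8)
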