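"""AUROC, bootstrap confidence intervals and triage confusion statistics.

AUROC is computed as the Mann-Whitney rank statistic: the fraction of
(positive, negative) patient pairs in which the positive scores higher,
ties counted 1/2 — identical to the trapezoidal area under the ROC curve.
Confidence intervals are percentile bootstrap over patient-level
resampling (default 1000 resamples, 95% level).
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .types import ConfusionStats, MetricCI, ThresholdPolicy, UndefinedMetricError

__all__ = [
    "auroc",
    "bootstrap_ci",
    "confusion_at",
    "confusion_from_counts",
]


def _split_arrays(scores, labels=None):
    if labels is None:  # list of PatientScore
        labels = np.array([p.label for p in scores], dtype=float)
        scores = np.array([p.score for p in scores], dtype=float)
    else:
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=float)
    return scores, labels


def auroc(scores, labels=None) -> float:
    """Probability a random positive outscores a random negative (ties 1/2).

    Accepts either a list of labeled ``PatientScore`` or parallel
    score/label arrays. Raises :class:`UndefinedMetricError` on
    single-class input.
    """
    s, y = _split_arrays(scores, labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC requires at least one patient of each class")
    ranks = rankdata(s)  # average ranks handle ties as half-wins
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def bootstrap_ci(
    scores,
    labels,
    metric: Callable[[np.ndarray, np.ndarray], float],
    n_boot: int = 1000,
    level: float = 0.95,
    rng: Optional[np.random.Generator] = None,
    stratified: bool = False,
) -> MetricCI:
    """Percentile bootstrap CI from patient-level resampling with replacement.

    Resamples on which the metric is undefined (e.g. a single-class draw
    for AUROC) are redrawn so that exactly ``n_boot`` effective resamples
    enter the quantiles; if more than half of all attempts fail, the CI is
    declared unobtainable. ``stratified=True`` resamples within each label
    class instead (off by default).
    """
    rng = np.random.default_rng() if rng is None else rng
    s, y = _split_arrays(scores, labels)
    n = len(s)
    point = float(metric(s, y))
    stats = np.empty(n_boot)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    n_redrawn = 0
    attempts = 0
    filled = 0
    # a metric undefined on more than half of the resamples cannot fill
    # n_boot draws within this attempt budget
    max_attempts = 2 * n_boot + 100
    while filled < n_boot:
        if attempts >= max_attempts:
            raise UndefinedMetricError(
                "metric undefined on more than half of bootstrap resamples"
            )
        attempts += 1
        if stratified:
            idx = np.concatenate(
                [
                    rng.choice(pos_idx, size=len(pos_idx), replace=True),
                    rng.choice(neg_idx, size=len(neg_idx), replace=True),
                ]
            )
        else:
            idx = rng.integers(0, n, size=n)
        try:
            stats[filled] = metric(s[idx], y[idx])
        except UndefinedMetricError:
            n_redrawn += 1
            continue
        filled += 1
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(stats, (alpha, 1.0 - alpha))
    return MetricCI(
        point=point,
        lower=float(lower),
        upper=float(upper),
        n_boot=n_boot,
        level=level,
        n_redrawn=n_redrawn,
    )


def confusion_at(scores, labels=None, policy: ThresholdPolicy = None) -> ConfusionStats:
    """Confusion counts of the rule "MSI if score >= policy.value"."""
    if policy is None:
        raise ValueError("a ThresholdPolicy is required")
    s, y = _split_arrays(scores, labels)
    if len(s) == 0:
        raise ValueError("empty cohort")
    if np.any(np.isnan(y)):
        raise ValueError("labels required for every scored patient")
    pred = s >= policy.value
    pos = y == 1
    return ConfusionStats(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def confusion_from_counts(tp: int, fp: int, tn: int, fn: int) -> ConfusionStats:
    """Build the triage statistics directly from confusion counts."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be nonnegative")
    return ConfusionStats(tp=tp, fp=fp, tn=tn, fn=fn)
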