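"""Back-substitution evaluation: confusion matrix and coincidence rates.

Re-classifying the derivation cohort with the rule derived from it
(resubstitution) gives the apparent accuracy. The field's customary summary
here is the per-class "coincidence rate" — the fraction of actual positives
(resp. negatives) that the rule reproduces — together with their arithmetic
mean. The mean of the two per-class rates is NOT overall accuracy when the
classes are unbalanced; both are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import stats

from .factors import Cohort, NEGATIVE, POSITIVE
from .frequency import round_half_away
from .scoring import ScoreTable, classify

__all__ = [
    "ConfusionMatrix",
    "CoincidenceReport",
    "GroupComparison",
    "back_substitute",
    "coincidence_rates",
    "compare_groups",
    "score_margins",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Back-substitution counts: actual class by predicted class."""

    tp: int  # actual +, predicted +
    fn: int  # actual +, predicted −
    fp: int  # actual −, predicted +
    tn: int  # actual −, predicted −

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def actual_positive(self) -> int:
        return self.tp + self.fn

    @property
    def actual_negative(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class CoincidenceReport:
    """Per-class coincidence rates (percent), their mean, and accuracy.

    ``rate_positive`` = 100·tp/(tp+fn), ``rate_negative`` = 100·tn/(fp+tn),
    each rounded half-away-from-zero to one decimal. ``mean_of_rates`` is the
    arithmetic mean of the two rounded per-class rates (the printed-table
    convention); ``overall_accuracy`` = 100·(tp+tn)/n. An empty actual class
    yields ``None`` for its rate.
    """

    rate_positive: float | None
    rate_negative: float | None
    mean_of_rates: float | None
    overall_accuracy: float

    def to_dict(self) -> dict:
        return {
            "rate_positive": self.rate_positive,
            "rate_negative": self.rate_negative,
            "mean_of_rates": self.mean_of_rates,
            "overall_accuracy": self.overall_accuracy,
        }


def back_substitute(score_table: ScoreTable, cohort: Cohort) -> ConfusionMatrix:
    """Classify every record of a labelled cohort and accumulate the cells."""
    if len(cohort) == 0:
        raise ValueError("cannot evaluate an empty cohort")
    tp = fn = fp = tn = 0
    for i, record in enumerate(cohort):
        if record.nodal_status is None:
            raise ValueError(f"record {i} has unknown nodal_status")
        predicted = classify(score_table, record).predicted
        if record.nodal_status == POSITIVE:
            if predicted == POSITIVE:
                tp += 1
            else:
                fn += 1
        else:
            if predicted == POSITIVE:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def coincidence_rates(matrix: ConfusionMatrix) -> CoincidenceReport:
    """Summarise a confusion matrix as printed-style coincidence rates."""
    if matrix.n == 0:
        raise ValueError("empty confusion matrix")
    rate_pos = (
        round_half_away(Fraction(100 * matrix.tp, matrix.actual_positive), 1)
        if matrix.actual_positive > 0
        else None
    )
    rate_neg = (
        round_half_away(Fraction(100 * matrix.tn, matrix.actual_negative), 1)
        if matrix.actual_negative > 0
        else None
    )
    mean = (
        round_half_away((rate_pos + rate_neg) / 2, 1)
        if rate_pos is not None and rate_neg is not None
        else None
    )
    overall = round_half_away(Fraction(100 * (matrix.tp + matrix.tn), matrix.n), 1)
    return CoincidenceReport(
        rate_positive=rate_pos,
        rate_negative=rate_neg,
        mean_of_rates=mean,
        overall_accuracy=overall,
    )


def score_margins(score_table: ScoreTable, cohort: Cohort) -> np.ndarray:
    """Per-patient score margins S+ − S− for a cohort."""
    return np.array(
        [
            (lambda c: c.s_positive - c.s_negative)(classify(score_table, r))
            for r in cohort
        ]
    )


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample rank-sum comparison of score margins between cohorts."""

    statistic: float
    pvalue: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.pvalue < self.alpha


def compare_groups(
    margins_a: Sequence[float], margins_b: Sequence[float], alpha: float = 0.05
) -> GroupComparison:
    """Compare per-patient score margins between two independent cohorts.

    Uses the two-sided Mann–Whitney rank-sum test, the appropriate rank test
    for independent groups of unequal size.
    """
    a = np.asarray(margins_a, dtype=float)
    b = np.asarray(margins_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 margin values")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(statistic=float(res.statistic), pvalue=float(res.pvalue), alpha=alpha)
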