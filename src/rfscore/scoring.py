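"""Risk-factor-score derivation and patient classification.

The discriminant is a maximum-likelihood classifier over six conditionally
independent categorical factors. For nodal class g the likelihood of a
patient's profile x = (x_1..x_6) is

    P_g(x) = prod_k P(x_k | Y_g),

and taking base-10 logarithms gives an additive score. Each level is scored

    score = (lg P(x_k | Y_g) + 1) * 10,

so that P = 0.1 scores 0 and P = 1 scores 10, and the patient's class score
S_g is the sum of the six level scores. The predicted class is the one with
the larger S (monotone in the likelihood, so the decision rule is unchanged
by the affine transform — up to table rounding).

Two scoring modes are supported. ``printed_1dp`` (default) rounds every table
cell half-away-from-zero to one decimal before summation, reproducing the
arithmetic of the printed score table; ``full_precision`` keeps unrounded
cells and agrees exactly with the rational likelihood-product argmax.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal
from fractions import Fraction
from typing import Mapping

import pandas as pd

from .factors import CLASSES, FACTORS, LEVELS, NEGATIVE, POSITIVE, PatientRecord
from .frequency import (
    ConditionalProbability,
    FrequencyTable,
    round_half_away,
)

__all__ = [
    "ScoreTable",
    "Classification",
    "ZeroFrequencyError",
    "level_score",
    "derive_score_table",
    "patient_score",
    "classify",
    "likelihood_product",
    "PRINTED_1DP",
    "FULL_PRECISION",
]

PRINTED_1DP = "printed_1dp"
FULL_PRECISION = "full_precision"
_MODES = (PRINTED_1DP, FULL_PRECISION)


class ZeroFrequencyError(ValueError):
    """A level unobserved in a class has log-likelihood −inf.

    Raised when deriving scores from a table with an empty cell and no
    smoothing; enable Laplace smoothing (alpha > 0) to score such tables.
    """


def level_score(p: ConditionalProbability | Fraction | float, rounding_mode: str = PRINTED_1DP) -> float:
    """Score one factor level for one class: (lg p + 1) × 10.

    Strictly increasing in p; anchors p=0.1 → 0, p=1 → 10, p=0.01 → −10.
    In ``printed_1dp`` mode the result is rounded half-away-from-zero to one
    decimal, matching the printed score table.
    """
    if rounding_mode not in _MODES:
        raise ValueError(f"unknown rounding_mode {rounding_mode!r}")
    value = float(p)
    if value <= 0:
        raise ZeroFrequencyError(
            "zero-frequency cell; enable smoothing (alpha > 0)"
        )
    score = (math.log10(value) + 1.0) * 10.0
    if rounding_mode == PRINTED_1DP:
        return round_half_away(score, 1)
    return score


@dataclass(frozen=True)
class ScoreTable:
    """Per-level scores for both nodal classes over all 17 factor levels."""

    scores: Mapping[tuple[str, str, str], float]
    rounding_mode: str = PRINTED_1DP
    smoothing: float = 0.0

    def __post_init__(self):
        if self.rounding_mode not in _MODES:
            raise ValueError(f"unknown rounding_mode {self.rounding_mode!r}")
        for factor in FACTORS:
            for level in LEVELS[factor]:
                for cls in CLASSES:
                    key = (factor, level, cls)
                    if key not in self.scores:
                        raise ValueError(f"missing score cell {key}")
                    if not math.isfinite(self.scores[key]):
                        raise ValueError(f"non-finite score in cell {key}")
        # cache decimal cell values; summing decimals keeps 1-dp sums exact
        object.__setattr__(
            self,
            "_decimals",
            {key: Decimal(repr(float(v))) for key, v in self.scores.items()},
        )

    def score(self, factor: str, level: str, cls: str) -> float:
        if level not in LEVELS.get(factor, ()):
            raise KeyError(f"unknown level {level!r} for factor {factor!r}")
        return self.scores[(factor, level, cls)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format dataframe in the layout of the printed score table."""
        rows = [
            {
                "factor": factor,
                "level": level,
                "positive": self.scores[(factor, level, POSITIVE)],
                "negative": self.scores[(factor, level, NEGATIVE)],
            }
            for factor in FACTORS
            for level in LEVELS[factor]
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, rounding_mode: str = PRINTED_1DP, smoothing: float = 0.0
    ) -> "ScoreTable":
        scores = {}
        for row in df.itertuples(index=False):
            scores[(row.factor, row.level, POSITIVE)] = float(row.positive)
            scores[(row.factor, row.level, NEGATIVE)] = float(row.negative)
        return cls(scores=scores, rounding_mode=rounding_mode, smoothing=smoothing)

    @classmethod
    def from_csv(cls, path, rounding_mode: str = PRINTED_1DP) -> "ScoreTable":
        return cls.from_frame(pd.read_csv(path), rounding_mode=rounding_mode)


def _smoothed_probability(
    table: FrequencyTable, factor: str, level: str, cls: str, alpha: float
) -> Fraction:
    count = table.counts[(factor, level, cls)]
    total = table.class_totals[cls]
    if alpha == 0:
        return Fraction(count, total)
    a = Fraction(alpha).limit_denominator(10**9)
    return (count + a) / (total + a * len(LEVELS[factor]))


def derive_score_table(
    table: FrequencyTable,
    rounding_mode: str = PRINTED_1DP,
    smoothing: float = 0.0,
) -> ScoreTable:
    """Derive the full score table from class-conditional frequencies.

    With ``smoothing`` alpha > 0, each conditional probability becomes
    (count + alpha) / (total + alpha·J_k) (Laplace), which removes
    zero-frequency singularities; the derivation cohort's table has no zero
    cells, so the default alpha = 0 suffices for it.
    """
    if smoothing < 0:
        raise ValueError("smoothing alpha must be >= 0")
    scores: dict[tuple[str, str, str], float] = {}
    for factor in FACTORS:
        for level in LEVELS[factor]:
            for cls in CLASSES:
                p = _smoothed_probability(table, factor, level, cls, smoothing)
                try:
                    scores[(factor, level, cls)] = level_score(p, rounding_mode)
                except ZeroFrequencyError as exc:
                    raise ZeroFrequencyError(
                        f"zero-frequency cell ({factor}, {level}, {cls}); "
                        "enable smoothing"
                    ) from exc
    return ScoreTable(scores=scores, rounding_mode=rounding_mode, smoothing=smoothing)


def patient_score(
    score_table: ScoreTable,
    record: PatientRecord,
    cls: str,
    priors: Mapping[str, float] | None = None,
) -> float:
    """Class score S_g: the sum of the six per-level scores for class g.

    Summation is done in decimal so that a table of one-decimal cells yields
    an exact one-decimal sum (8.6 + 7.5 + 2.5 + 8.4 + 9.7 + 4.6 = 41.3, not
    41.300000000000004).

    The discriminant is likelihood-only by default: class prevalence does not
    enter. Passing ``priors`` (a mapping class → prior probability) adds
    10·lg(prior_g), turning the comparison into a posterior one for
    sensitivity analysis.
    """
    if cls not in CLASSES:
        raise KeyError(f"unknown class {cls!r}")
    profile = record.profile
    cells = score_table._decimals
    total = Decimal(0)
    for factor, level in zip(FACTORS, profile):
        total += cells[(factor, level, cls)]
    if priors is not None:
        prior = priors[cls]
        if not (0 < prior <= 1):
            raise ValueError(f"prior for {cls} must be in (0, 1]: {prior!r}")
        return float(total) + 10.0 * math.log10(prior)
    return float(total)


@dataclass(frozen=True)
class Classification:
    """Both class scores, the predicted class, and a tie flag."""

    s_positive: float
    s_negative: float
    predicted: str
    tie: bool


def classify(
    score_table: ScoreTable,
    record: PatientRecord,
    priors: Mapping[str, float] | None = None,
) -> Classification:
    """Predict nodal status: the class with the larger score wins.

    An exact tie predicts positive (the clinically conservative call) and is
    flagged.
    """
    s_pos = patient_score(score_table, record, POSITIVE, priors=priors)
    s_neg = patient_score(score_table, record, NEGATIVE, priors=priors)
    tie = s_pos == s_neg
    predicted = POSITIVE if s_pos >= s_neg else NEGATIVE
    return Classification(s_positive=s_pos, s_negative=s_neg, predicted=predicted, tie=tie)


def likelihood_product(
    table: FrequencyTable, record: PatientRecord, cls: str
) -> Fraction:
    """Exact class-conditional likelihood prod_k P(x_k | Y_g).

    Computed in rational arithmetic; serves as the exact oracle for the
    score-based decision rule (argmax of the product equals argmax of the
    unrounded score sum).
    """
    if cls not in CLASSES:
        raise KeyError(f"unknown class {cls!r}")
    product = Fraction(1)
    for factor, level in zip(FACTORS, record.profile):
        product *= Fraction(
            table.counts[(factor, level, cls)], table.class_totals[cls]
        )
    return product
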