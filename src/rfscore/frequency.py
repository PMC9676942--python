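"""Class-conditional frequency tabulation of the six risk factors.

Counts how often each factor level occurs among nodal-positive and
nodal-negative patients and exposes the conditional probabilities
P(X_kj | Y_g) = count / class total as exact rationals, plus per-level
marginal metastasis rates in percent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Mapping

import pandas as pd

from .factors import CLASSES, FACTORS, LEVELS, NEGATIVE, POSITIVE, Cohort

__all__ = [
    "FrequencyTable",
    "ConditionalProbability",
    "tabulate",
    "conditional_probability",
    "marginal_metastasis_rates",
    "metastasis_rate",
    "round_half_away",
]


def round_half_away(value: float | Fraction, ndigits: int = 1) -> float:
    """Round half away from zero to *ndigits* decimals.

    This is the rounding convention of printed clinical tables (0.05 → 0.1,
    −0.35 → −0.4), unlike banker's rounding of the builtin ``round``.
    """
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(float(value)))
    q = Decimal(1).scaleb(-ndigits)
    return float(dec.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConditionalProbability:
    """An exact conditional probability count/total with its provenance."""

    numerator: int
    denominator: int

    @property
    def value(self) -> Fraction:
        return Fraction(self.numerator, self.denominator)

    def __float__(self) -> float:
        return self.numerator / self.denominator


@dataclass(frozen=True)
class FrequencyTable:
    """Level-by-class counts for all six factors.

    ``counts[(factor, level, cls)]`` is the number of patients of nodal class
    ``cls`` ("positive"/"negative") with that factor level; ``class_totals``
    are the per-class patient counts. Every factor's counts sum to the class
    total, so conditional probabilities per factor sum to exactly 1.
    """

    counts: Mapping[tuple[str, str, str], int]
    class_totals: Mapping[str, int]

    def __post_init__(self):
        for cls in CLASSES:
            if cls not in self.class_totals:
                raise ValueError(f"missing class total for {cls!r}")
            if self.class_totals[cls] <= 0:
                raise ValueError(f"class {cls} empty")
        for factor in FACTORS:
            for cls in CLASSES:
                s = 0
                for level in LEVELS[factor]:
                    c = self.counts.get((factor, level, cls))
                    if c is None:
                        raise ValueError(f"missing cell ({factor}, {level}, {cls})")
                    if c < 0:
                        raise ValueError(f"negative count in ({factor}, {level}, {cls})")
                    s += c
                if s != self.class_totals[cls]:
                    raise ValueError(
                        f"factor {factor!r} counts for class {cls} sum to {s}, "
                        f"expected {self.class_totals[cls]}"
                    )

    @property
    def n(self) -> int:
        return self.class_totals[POSITIVE] + self.class_totals[NEGATIVE]

    # ---- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        out: dict = {
            factor: {
                level: {cls: self.counts[(factor, level, cls)] for cls in CLASSES}
                for level in LEVELS[factor]
            }
            for factor in FACTORS
        }
        out["class_totals"] = dict(self.class_totals)
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "FrequencyTable":
        counts = {
            (factor, level, c): int(d[factor][level][c])
            for factor in FACTORS
            for level in LEVELS[factor]
            for c in CLASSES
        }
        totals = {c: int(d["class_totals"][c]) for c in CLASSES}
        return cls(counts=counts, class_totals=totals)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FrequencyTable":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_frame(self) -> pd.DataFrame:
        """Long-format dataframe mirroring the printed frequency table."""
        rows = [
            {
                "factor": factor,
                "level": level,
                "positive": self.counts[(factor, level, POSITIVE)],
                "negative": self.counts[(factor, level, NEGATIVE)],
            }
            for factor in FACTORS
            for level in LEVELS[factor]
        ]
        return pd.DataFrame(rows)


def tabulate(cohort: Cohort) -> FrequencyTable:
    """Build the class-conditional frequency table from a labelled cohort.

    Every record must carry a known nodal status and all six categories;
    an empty class is an error (the discriminant needs both classes).
    """
    if len(cohort) == 0:
        raise ValueError("cannot tabulate an empty cohort")
    counts = {
        (factor, level, cls): 0
        for factor in FACTORS
        for level in LEVELS[factor]
        for cls in CLASSES
    }
    totals = {cls: 0 for cls in CLASSES}
    for i, record in enumerate(cohort):
        if record.nodal_status is None:
            raise ValueError(f"record {i} has unknown nodal_status")
        profile = record.profile
        totals[record.nodal_status] += 1
        for factor, level in zip(FACTORS, profile):
            counts[(factor, level, record.nodal_status)] += 1
    for cls in CLASSES:
        if totals[cls] == 0:
            raise ValueError(f"class {cls} empty")
    return FrequencyTable(counts=counts, class_totals=totals)


def conditional_probability(
    table: FrequencyTable, factor: str, level: str, cls: str
) -> ConditionalProbability:
    """P(level of factor | nodal class) as an exact rational."""
    if factor not in FACTORS:
        raise KeyError(f"unknown factor {factor!r}")
    if level not in LEVELS[factor]:
        raise KeyError(f"unknown level {level!r} for factor {factor!r}")
    if cls not in CLASSES:
        raise KeyError(f"unknown class {cls!r}")
    return ConditionalProbability(
        numerator=table.counts[(factor, level, cls)],
        denominator=table.class_totals[cls],
    )


def metastasis_rate(n_positive: int, n_negative: int) -> float | None:
    """Metastasis rate in percent, printed-style (1 decimal, half away).

    Returns ``None`` (undefined) when no patients carry the level.
    """
    total = n_positive + n_negative
    if total == 0:
        return None
    return round_half_away(Fraction(100 * n_positive, total), 1)


def marginal_metastasis_rates(
    table: FrequencyTable, factor: str
) -> dict[str, float | None]:
    """Per-level metastasis rates for one factor, in percent.

    rate(level) = 100 · n(level, +) / (n(level, +) + n(level, −)); levels
    observed in neither class map to ``None``.
    """
    if factor not in FACTORS:
        raise KeyError(f"unknown factor {factor!r}")
    return {
        level: metastasis_rate(
            table.counts[(factor, level, POSITIVE)],
            table.counts[(factor, level, NEGATIVE)],
        )
        for level in LEVELS[factor]
    }
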