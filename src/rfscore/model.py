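"""Model/results interface tying the pipeline together.

`CentralLNMDiscriminant` is built from a labelled cohort (or directly from a
frequency table when only aggregate counts are available, as for the
published derivation cohort). `fit()` derives the score table and returns a
`DiscriminantResults` object that classifies new patients, evaluates by
back-substitution, and renders a summary in the style of the printed tables.

Example
-------
>>> from rfscore.datasets import load_retrospective_counts
>>> from rfscore.model import CentralLNMDiscriminant
>>> res = CentralLNMDiscriminant.from_frequency_table(load_retrospective_counts()).fit()
>>> res.score_table.score("sex", "female", "positive")
8.6
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .evaluation import (
    CoincidenceReport,
    ConfusionMatrix,
    back_substitute,
    coincidence_rates,
)
from .factors import CLASSES, FACTORS, LEVELS, Cohort, PatientRecord
from .frequency import FrequencyTable, marginal_metastasis_rates, tabulate
from .scoring import (
    PRINTED_1DP,
    Classification,
    ScoreTable,
    classify,
    derive_score_table,
)

__all__ = ["CentralLNMDiscriminant", "DiscriminantResults"]


class CentralLNMDiscriminant:
    """Maximum-likelihood discriminant for central-compartment nodal status.

    Parameters
    ----------
    cohort : Cohort, optional
        Labelled derivation cohort; tabulated on construction.
    freq_table : FrequencyTable, optional
        Pre-tabulated counts (mutually exclusive with *cohort*).
    """

    def __init__(self, cohort: Cohort | None = None, freq_table: FrequencyTable | None = None):
        if (cohort is None) == (freq_table is None):
            raise ValueError("provide exactly one of cohort or freq_table")
        self.cohort = cohort
        self.freq_table = freq_table if freq_table is not None else tabulate(cohort)

    @classmethod
    def from_frequency_table(cls, table: FrequencyTable) -> "CentralLNMDiscriminant":
        return cls(freq_table=table)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "") -> "CentralLNMDiscriminant":
        return cls(cohort=Cohort.from_dataframe(df, label=label))

    @classmethod
    def from_csv(cls, path) -> "CentralLNMDiscriminant":
        return cls(cohort=Cohort.from_csv(path))

    def fit(self, rounding_mode: str = PRINTED_1DP, smoothing: float = 0.0) -> "DiscriminantResults":
        """Derive the score table and return the results object."""
        score_table = derive_score_table(
            self.freq_table, rounding_mode=rounding_mode, smoothing=smoothing
        )
        return DiscriminantResults(model=self, score_table=score_table)


@dataclass
class DiscriminantResults:
    """Fitted score table plus prediction and evaluation methods."""

    model: CentralLNMDiscriminant
    score_table: ScoreTable

    @property
    def freq_table(self) -> FrequencyTable:
        return self.model.freq_table

    def predict(self, record: PatientRecord) -> Classification:
        """Score and classify one patient."""
        return classify(self.score_table, record)

    def predict_cohort(self, cohort: Cohort) -> pd.DataFrame:
        """Cohort dataframe with s_positive, s_negative, predicted, tie."""
        df = cohort.to_dataframe()
        cls = [classify(self.score_table, r) for r in cohort]
        df["s_positive"] = [c.s_positive for c in cls]
        df["s_negative"] = [c.s_negative for c in cls]
        df["predicted"] = [c.predicted for c in cls]
        df["tie"] = [c.tie for c in cls]
        return df

    def evaluate(self, cohort: Cohort | None = None) -> tuple[ConfusionMatrix, CoincidenceReport]:
        """Back-substitute a cohort (default: the derivation cohort)."""
        if cohort is None:
            cohort = self.model.cohort
        if cohort is None:
            raise ValueError(
                "model was built from aggregate counts; pass a cohort to evaluate"
            )
        matrix = back_substitute(self.score_table, cohort)
        return matrix, coincidence_rates(matrix)

    def marginal_rates(self, factor: str) -> dict[str, float | None]:
        """Per-level metastasis rates (%) for one factor."""
        return marginal_metastasis_rates(self.freq_table, factor)

    def summary(self) -> str:
        """Plain-text summary: counts, scores, and marginal rates."""
        ft, st = self.freq_table, self.score_table
        lines = [
            "Central compartment LNM risk-factor-score discriminant",
            "=" * 58,
            f"Derivation counts: {ft.class_totals['positive']} LNM-positive, "
            f"{ft.class_totals['negative']} LNM-negative (n = {ft.n})",
            f"Scoring mode: {st.rounding_mode} (smoothing alpha = {st.smoothing})",
            "",
            f"{'factor':<14}{'level':<10}{'n+':>5}{'n-':>5}"
            f"{'score+':>8}{'score-':>8}{'LNM %':>8}",
            "-" * 58,
        ]
        for factor in FACTORS:
            rates = marginal_metastasis_rates(ft, factor)
            for level in LEVELS[factor]:
                rate = rates[level]
                lines.append(
                    f"{factor:<14}{level:<10}"
                    f"{ft.counts[(factor, level, 'positive')]:>5}"
                    f"{ft.counts[(factor, level, 'negative')]:>5}"
                    f"{st.scores[(factor, level, 'positive')]:>8.1f}"
                    f"{st.scores[(factor, level, 'negative')]:>8.1f}"
                    f"{rate if rate is not None else float('nan'):>8.1f}"
                )
        return "\n".join(lines)
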