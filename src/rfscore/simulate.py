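"""Synthetic patient cohorts under the class-conditional independence model.

The score's likelihood product assumes the six factors are independent given
nodal status; the generator samples from exactly that model. Each patient
first draws a nodal class (Bernoulli with the cohort prevalence), then each
factor level independently from that class's level probabilities. Default
parameters reproduce the derivation study's conditions: n = 412, prevalence
197/412, and level probabilities equal to the published class-conditional
relative frequencies.

Only marginal frequencies of the real cohorts were ever published, so the
synthetic joint distribution is the independence model by construction —
realistic per factor, not guaranteed realistic jointly.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .factors import CLASSES, FACTORS, LEVELS, NEGATIVE, POSITIVE, Cohort, PatientRecord
from .frequency import FrequencyTable

__all__ = [
    "GeneratorParams",
    "RAW_AGE_RANGES",
    "RAW_DIAMETER_RANGES",
    "default_params",
    "generate_cohort",
    "enumerate_profiles",
    "write_cohort_with_provenance",
]

#: Integer-year age range sampled per age level; the open bins are truncated
#: at the derivation study's observed extremes (ages 14–81).
RAW_AGE_RANGES: dict[str, tuple[int, int]] = {"lt45": (14, 44), "ge45": (45, 81)}

#: Diameter range (cm, on a 0.1 cm grid) per size level; open bins truncated
#: at the observed extremes (0.2–3.8 cm).
RAW_DIAMETER_RANGES: dict[str, tuple[float, float]] = {
    "lt0.7": (0.2, 0.6),
    "0.7-1.0": (0.7, 0.9),
    "1.0-1.5": (1.0, 1.4),
    "1.5-2.0": (1.5, 1.9),
    "ge2.0": (2.0, 3.8),
}


@dataclass(frozen=True)
class GeneratorParams:
    """Full parameterization of the synthetic-cohort generator."""

    n: int
    prevalence: float
    level_probs: Mapping[tuple[str, str], tuple[float, ...]]
    emit_raw: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"n must be >= 1: {self.n}")
        # prevalence 1 is allowed as a degenerate all-positive cohort
        if not (0 < self.prevalence <= 1):
            raise ValueError(f"prevalence must be in (0, 1]: {self.prevalence}")
        for factor in FACTORS:
            for cls in CLASSES:
                probs = self.level_probs.get((factor, cls))
                if probs is None:
                    raise ValueError(f"missing level_probs for ({factor}, {cls})")
                if len(probs) != len(LEVELS[factor]):
                    raise ValueError(
                        f"level_probs for ({factor}, {cls}) has length "
                        f"{len(probs)}, expected {len(LEVELS[factor])}"
                    )
                if any(p < 0 for p in probs):
                    raise ValueError(f"negative probability in ({factor}, {cls})")
                if abs(sum(probs) - 1.0) > 1e-12:
                    raise ValueError(
                        f"level_probs for ({factor}, {cls}) sum to {sum(probs)}"
                    )

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "prevalence": self.prevalence,
            "emit_raw": self.emit_raw,
            "seed": self.seed,
            "level_probs": {
                f"{factor}|{cls}": list(self.level_probs[(factor, cls)])
                for factor in FACTORS
                for cls in CLASSES
            },
        }


def default_params(
    table: FrequencyTable,
    n: int = 412,
    prevalence: float | None = None,
    seed: int = 0,
    emit_raw: bool = False,
) -> GeneratorParams:
    """Generator parameters matching a frequency table's relative frequencies.

    With no overrides this emulates the derivation cohort: n = 412 and
    prevalence 197/412 ≈ 0.4782.
    """
    if prevalence is None:
        prevalence = table.class_totals[POSITIVE] / table.n
    level_probs = {
        (factor, cls): tuple(
            table.counts[(factor, level, cls)] / table.class_totals[cls]
            for level in LEVELS[factor]
        )
        for factor in FACTORS
        for cls in CLASSES
    }
    return GeneratorParams(
        n=n,
        prevalence=prevalence,
        level_probs=level_probs,
        emit_raw=emit_raw,
        seed=seed,
    )


def generate_cohort(params: GeneratorParams, label: str = "synthetic") -> Cohort:
    """Draw a reproducible synthetic cohort from the independence model."""
    rng = np.random.default_rng(params.seed)
    n = params.n
    is_positive = rng.random(n) < params.prevalence
    status = np.where(is_positive, POSITIVE, NEGATIVE)

    levels: dict[str, np.ndarray] = {}
    for factor in FACTORS:
        toks = np.array(LEVELS[factor], dtype=object)
        idx = np.zeros(n, dtype=np.int64)
        for cls, mask in ((POSITIVE, is_positive), (NEGATIVE, ~is_positive)):
            m = int(mask.sum())
            if m:
                idx[mask] = rng.choice(
                    len(toks), size=m, p=np.asarray(params.level_probs[(factor, cls)])
                )
        levels[factor] = toks[idx]

    ages = diams = None
    if params.emit_raw:
        ages = np.empty(n, dtype=np.int64)
        for tok, (lo, hi) in RAW_AGE_RANGES.items():
            mask = levels["age"] == tok
            ages[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
        diams = np.empty(n, dtype=np.float64)
        for tok, (lo, hi) in RAW_DIAMETER_RANGES.items():
            mask = levels["diameter"] == tok
            steps = int(round((hi - lo) / 0.1))
            diams[mask] = lo + 0.1 * rng.integers(0, steps + 1, size=int(mask.sum()))
        diams = np.round(diams, 1)

    records = [
        PatientRecord(
            sex=levels["sex"][i],
            age_cat=levels["age"][i],
            diameter_cat=levels["diameter"][i],
            ecs=levels["ecs"][i],
            multifocality=levels["multifocality"][i],
            location=levels["location"][i],
            age_years=int(ages[i]) if ages is not None else None,
            diameter_cm=float(diams[i]) if diams is not None else None,
            nodal_status=str(status[i]),
        )
        for i in range(n)
    ]
    # records are valid by construction; skip per-record re-validation
    return Cohort(records=records, label=label)


def enumerate_profiles() -> list[tuple[str, ...]]:
    """All 2·2·5·2·2·4 = 320 factor-level profiles, lexicographic in the
    canonical factor and level order."""
    return list(itertools.product(*(LEVELS[f] for f in FACTORS)))


def write_cohort_with_provenance(cohort: Cohort, params: GeneratorParams, csv_path) -> None:
    """Write the cohort CSV plus a sidecar JSON with the full parameters."""
    cohort.to_csv(csv_path)
    sidecar = str(csv_path) + ".params.json"
    with open(sidecar, "w") as fh:
        json.dump(params.to_dict(), fh, indent=1)
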