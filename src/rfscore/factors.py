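"""Domain model for the six categorical risk factors and patient records.

The discriminant works on six preoperative factors for papillary thyroid
carcinoma: sex, age group, maximum tumour diameter, extracapsular spread
(ECS), multifocality, and tumour location within the gland. Each factor is
categorical with a fixed level set (2, 2, 5, 2, 2 and 4 levels; 17 levels in
total). Levels are encoded as exact ASCII tokens so that file round-trips are
unambiguous (no Unicode dashes or ``≥`` signs in data files).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "FACTORS",
    "LEVELS",
    "CLASSES",
    "POSITIVE",
    "NEGATIVE",
    "PatientRecord",
    "Cohort",
    "ValidationError",
    "categorize_age",
    "categorize_diameter",
    "validate_record",
]

#: Factor names in canonical order (the order k = 1..6 of the score sum).
FACTORS: tuple[str, ...] = (
    "sex",
    "age",
    "diameter",
    "ecs",
    "multifocality",
    "location",
)

#: Level tokens per factor, in canonical order.
LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "age": ("lt45", "ge45"),
    "diameter": ("lt0.7", "0.7-1.0", "1.0-1.5", "1.5-2.0", "ge2.0"),
    "ecs": ("presence", "absence"),
    "multifocality": ("presence", "absence"),
    "location": ("upper", "middle", "lower", "isthmus"),
}

POSITIVE = "positive"
NEGATIVE = "negative"
#: Nodal-status classes: central compartment lymph node metastasis + / −.
CLASSES: tuple[str, str] = (POSITIVE, NEGATIVE)

# Diameter bin edges (cm); bins are lower-inclusive half-open so that a
# tumour of exactly 1.0 cm falls in "1.0-1.5" and 1.5 cm in "1.5-2.0",
# consistent with the end labels "<0.7" and ">=2.0".
_DIAMETER_EDGES: tuple[float, ...] = (0.7, 1.0, 1.5, 2.0)

AGE_CUTOFF = 45


class ValidationError(ValueError):
    """Raised when a record or value violates the domain invariants.

    Carries a list of human-readable messages, one per violated invariant,
    each naming the offending field and value.
    """

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


def categorize_age(age_years: int) -> str:
    """Map an age in whole years onto the ``lt45`` / ``ge45`` dichotomy.

    The cut-off of 45 years follows the TNM-staging convention for
    differentiated thyroid carcinoma.
    """
    if not (0 <= age_years <= 120):
        raise ValidationError([f"age_years out of range [0, 120]: {age_years!r}"])
    return "lt45" if age_years < AGE_CUTOFF else "ge45"


def categorize_diameter(diameter_cm: float) -> str:
    """Map a maximum tumour diameter in cm onto the five size bins.

    Bins are lower-inclusive half-open intervals
    [0, 0.7), [0.7, 1.0), [1.0, 1.5), [1.5, 2.0), [2.0, inf).
    """
    if not (0 < diameter_cm < 10) or math.isnan(diameter_cm):
        raise ValidationError(
            [f"diameter_cm out of range (0, 10): {diameter_cm!r}"]
        )
    for edge, level in zip(_DIAMETER_EDGES, LEVELS["diameter"]):
        if diameter_cm < edge:
            return level
    return LEVELS["diameter"][-1]


@dataclass(frozen=True)
class PatientRecord:
    """One patient's factor levels plus (optionally) the true nodal status.

    Raw values (``age_years``, ``diameter_cm``) and categorical levels may be
    given independently; when both are present they must agree, and when only
    the raw value is present :func:`validate_record` derives the category.
    ``nodal_status`` is ``None`` for patients still to be classified.
    ``multifocal_across_poles`` marks the exclusion criterion (multiple foci
    in two or more different parts of the gland); such records are rejected.
    """

    sex: str | None = None
    age_cat: str | None = None
    diameter_cat: str | None = None
    ecs: str | None = None
    multifocality: str | None = None
    location: str | None = None
    age_years: int | None = None
    diameter_cm: float | None = None
    nodal_status: str | None = None
    multifocal_across_poles: bool = False

    def validated(self) -> "PatientRecord":
        """Shorthand for :func:`validate_record` on this record."""
        return validate_record(self)

    def level(self, factor: str) -> str | None:
        """Return this record's level token for *factor*."""
        attr = {"age": "age_cat", "diameter": "diameter_cat"}.get(factor, factor)
        return getattr(self, attr)

    @property
    def profile(self) -> tuple[str, ...]:
        """The six level tokens in canonical factor order."""
        levels = tuple(self.level(f) for f in FACTORS)
        missing = [f for f, l in zip(FACTORS, levels) if l is None]
        if missing:
            raise ValidationError([f"missing category for factor {f!r}" for f in missing])
        return levels  # type: ignore[return-value]


def validate_record(record: PatientRecord) -> PatientRecord:
    """Validate a record and fill derived categories from raw values.

    Returns a new record with ``age_cat`` / ``diameter_cat`` derived from the
    raw values where absent. Raises :class:`ValidationError` listing every
    violated invariant (unknown level token, raw/category inconsistency,
    out-of-range raw value, the multifocal-across-poles exclusion).
    Validation is idempotent.
    """
    errors: list[str] = []
    updates: dict[str, object] = {}

    if record.multifocal_across_poles:
        errors.append(
            "multifocal_across_poles: record meets the exclusion criterion "
            "(multiple foci in two or more different parts)"
        )

    if record.age_years is not None:
        try:
            derived = categorize_age(record.age_years)
        except ValidationError as exc:
            errors.extend(exc.errors)
        else:
            if record.age_cat is None:
                updates["age_cat"] = derived
            elif record.age_cat != derived:
                errors.append(
                    f"age_cat inconsistent: {record.age_cat!r} but "
                    f"age_years={record.age_years} implies {derived!r}"
                )

    if record.diameter_cm is not None:
        try:
            derived = categorize_diameter(record.diameter_cm)
        except ValidationError as exc:
            errors.extend(exc.errors)
        else:
            if record.diameter_cat is None:
                updates["diameter_cat"] = derived
            elif record.diameter_cat != derived:
                errors.append(
                    f"diameter_cat inconsistent: {record.diameter_cat!r} but "
                    f"diameter_cm={record.diameter_cm} implies {derived!r}"
                )

    candidate = replace(record, **updates) if updates else record

    for factor in FACTORS:
        lvl = candidate.level(factor)
        if lvl is not None and lvl not in LEVELS[factor]:
            errors.append(f"{factor}: unknown level {lvl!r}")

    if candidate.nodal_status is not None and candidate.nodal_status not in CLASSES:
        errors.append(f"nodal_status: unknown class {candidate.nodal_status!r}")

    if errors:
        raise ValidationError(errors)
    return candidate


#: Cohort CSV column order.
CSV_COLUMNS = (
    "sex",
    "age_years",
    "age_cat",
    "diameter_cm",
    "diameter_cat",
    "ecs",
    "multifocality",
    "location",
    "nodal_status",
)


@dataclass
class Cohort:
    """An ordered collection of validated patient records."""

    records: list[PatientRecord] = field(default_factory=list)
    label: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    @classmethod
    def from_records(
        cls, records: Iterable[PatientRecord], label: str = "", validate: bool = True
    ) -> "Cohort":
        recs = list(records)
        if validate:
            recs = [validate_record(r) for r in recs]
        return cls(records=recs, label=label)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "") -> "Cohort":
        """Build a cohort from a dataframe using the standard CSV columns."""
        records = []
        for row in df.itertuples(index=False):
            d = row._asdict()

            def _opt(key):
                v = d.get(key)
                if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
                    return None
                return v

            age = _opt("age_years")
            diam = _opt("diameter_cm")
            records.append(
                PatientRecord(
                    sex=_opt("sex"),
                    age_years=int(age) if age is not None else None,
                    age_cat=_opt("age_cat"),
                    diameter_cm=float(diam) if diam is not None else None,
                    diameter_cat=_opt("diameter_cat"),
                    ecs=_opt("ecs"),
                    multifocality=_opt("multifocality"),
                    location=_opt("location"),
                    nodal_status=_opt("nodal_status"),
                )
            )
        return cls.from_records(records, label=label)

    @classmethod
    def from_csv(cls, path, label: str | None = None) -> "Cohort":
        df = pd.read_csv(path, dtype={c: "object" for c in CSV_COLUMNS})
        if label is None:
            label = str(path)
        # raw columns back to numbers where present
        for col in ("age_years", "diameter_cm"):
            if col in df.columns:
                df[col] = pd.to_numeric(df[col], errors="coerce")
        return cls.from_dataframe(df, label=label)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "sex": r.sex,
                    "age_years": r.age_years,
                    "age_cat": r.age_cat,
                    "diameter_cm": r.diameter_cm,
                    "diameter_cat": r.diameter_cat,
                    "ecs": r.ecs,
                    "multifocality": r.multifocality,
                    "location": r.location,
                    "nodal_status": r.nodal_status,
                }
            )
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)
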