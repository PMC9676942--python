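import pytest

from rfscore.datasets import load_retrospective_counts
from rfscore.factors import PatientRecord
from rfscore.scoring import FULL_PRECISION, derive_score_table


@pytest.fixture(scope="session")
def retro_table():
    """Class-conditional counts of the published derivation cohort."""
    return load_retrospective_counts()


@pytest.fixture(scope="session")
def scores_1dp(retro_table):
    """Score table in the printed one-decimal mode (the default)."""
    return derive_score_table(retro_table)


@pytest.fixture(scope="session")
def scores_full(retro_table):
    """Unrounded score table for oracle comparisons."""
    return derive_score_table(retro_table, rounding_mode=FULL_PRECISION)


@pytest.fixture
def toy_records():
    """Three hand-countable records: two identical positives, one negative."""
    pos = PatientRecord(
        sex="female", age_cat="lt45", diameter_cat="lt0.7",
        ecs="absence", multifocality="absence", location="upper",
        nodal_status="positive",
    )
    neg = PatientRecord(
        sex="male", age_cat="ge45", diameter_cat="ge2.0",
        ecs="presence", multifocality="presence", location="lower",
        nodal_status="negative",
    )
    return [pos, neg, pos]
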