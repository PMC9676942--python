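"""Score derivation, patient scoring, classification, and its exact oracle."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rfscore.factors import CLASSES, FACTORS, LEVELS, Cohort, PatientRecord
from rfscore.frequency import tabulate
from rfscore.published import PUBLISHED_SCORES, WORKED_EXAMPLE_PATIENT
from rfscore.scoring import (
    FULL_PRECISION,
    PRINTED_1DP,
    ScoreTable,
    ZeroFrequencyError,
    classify,
    derive_score_table,
    level_score,
    likelihood_product,
    patient_score,
)
from rfscore.simulate import default_params, enumerate_profiles, generate_cohort


def record_from_profile(profile, status=None):
    return PatientRecord(
        sex=profile[0], age_cat=profile[1], diameter_cat=profile[2],
        ecs=profile[3], multifocality=profile[4], location=profile[5],
        nodal_status=status,
    )


class TestLevelScore:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.1, 0.0), (1.0, 10.0), (0.01, -10.0)],
    )
    def test_scale_anchors_exact(self, p, expected):
        assert level_score(p, FULL_PRECISION) == pytest.approx(expected, abs=1e-12)
        assert level_score(p, PRINTED_1DP) == expected

    @pytest.mark.parametrize(
        "p,expected",
        [(Fraction(144, 197), 8.6), (Fraction(8, 215), -4.3), (0.5, 7.0)],
    )
    def test_printed_mode_one_decimal(self, p, expected):
        assert level_score(p, PRINTED_1DP) == expected

    def test_zero_probability_is_an_explicit_error(self):
        with pytest.raises(ZeroFrequencyError, match="smoothing"):
            level_score(0.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        st.floats(min_value=1e-6, max_value=1.0),
        st.floats(min_value=1e-6, max_value=1.0),
    )
    def test_strictly_increasing_in_p(self, a, b):
        if a == b:
            return
        lo, hi = sorted((a, b))
        assert level_score(lo, FULL_PRECISION) < level_score(hi, FULL_PRECISION)


class TestDeriveScoreTable:
    def test_reproduces_all_34_published_cells(self, scores_1dp):
        for (factor, level), (sp, sn) in PUBLISHED_SCORES.items():
            assert scores_1dp.score(factor, level, "positive") == sp, (factor, level)
            assert scores_1dp.score(factor, level, "negative") == sn, (factor, level)

    def test_zero_cell_requires_smoothing(self, toy_records):
        table = tabulate(Cohort.from_records(toy_records))
        with pytest.raises(ZeroFrequencyError, match=r"\(sex, "):
            derive_score_table(table)
        smoothed = derive_score_table(table, smoothing=1.0)
        assert np.isfinite(smoothed.score("sex", "male", "positive"))

    def test_smoothing_uses_laplace_formula(self, toy_records):
        table = tabulate(Cohort.from_records(toy_records))
        st_ = derive_score_table(table, rounding_mode=FULL_PRECISION, smoothing=1.0)
        # (count + 1) / (total + J_k): sex female positive = (2+1)/(2+2)
        assert st_.score("sex", "female", "positive") == pytest.approx(
            level_score(Fraction(3, 4), FULL_PRECISION)
        )

    def test_metadata_recorded(self, scores_1dp):
        assert scores_1dp.rounding_mode == PRINTED_1DP
        assert scores_1dp.smoothing == 0.0

    def test_csv_round_trip(self, scores_1dp, tmp_path):
        path = tmp_path / "scores.csv"
        scores_1dp.to_csv(path)
        back = ScoreTable.from_csv(path)
        assert dict(back.scores) == dict(scores_1dp.scores)


class TestPatientScore:
    def test_worked_example_exact(self, scores_1dp):
        patient = WORKED_EXAMPLE_PATIENT.validated()
        assert patient_score(scores_1dp, patient, "positive") == 41.3
        assert patient_score(scores_1dp, patient, "negative") == 37.0

    def test_six_cell_sum(self, scores_1dp):
        # 9.2 + 7.5 + 5.4 + 9.6 + 9.8 + 7.1 from the published table
        rec = record_from_profile(("female", "ge45", "lt0.7", "absence", "absence", "middle"))
        assert patient_score(scores_1dp, rec, "negative") == 48.6

    def test_missing_category_names_the_factor(self, scores_1dp):
        rec = PatientRecord(sex="female", age_cat="lt45", diameter_cat="lt0.7",
                            ecs="absence", multifocality="absence")
        with pytest.raises(Exception, match="location"):
            patient_score(scores_1dp, rec, "positive")

    def test_prior_mode_shifts_by_10_lg_prior(self, scores_1dp):
        patient = WORKED_EXAMPLE_PATIENT.validated()
        base = patient_score(scores_1dp, patient, "positive")
        with_prior = patient_score(
            scores_1dp, patient, "positive", priors={"positive": 0.1, "negative": 0.9}
        )
        assert with_prior == pytest.approx(base - 10.0)


class TestClassify:
    def test_worked_example_predicted_positive(self, scores_1dp):
        c = classify(scores_1dp, WORKED_EXAMPLE_PATIENT.validated())
        assert (c.s_positive, c.s_negative) == (41.3, 37.0)
        assert c.predicted == "positive" and not c.tie

    def test_low_risk_profile_predicted_negative(self, scores_1dp):
        rec = record_from_profile(("female", "ge45", "lt0.7", "absence", "absence", "upper"))
        c = classify(scores_1dp, rec)
        assert (c.s_positive, c.s_negative) == (33.9, 45.0)
        assert c.predicted == "negative"

    def test_tie_predicts_positive_and_is_flagged(self):
        scores = {
            (factor, level, cls): 1.0
            for factor in FACTORS for level in LEVELS[factor] for cls in CLASSES
        }
        table = ScoreTable(scores=scores)
        c = classify(table, record_from_profile(enumerate_profiles()[0]))
        assert c.tie and c.predicted == "positive"

    def test_overwhelming_prior_flips_decision(self, scores_1dp):
        patient = WORKED_EXAMPLE_PATIENT.validated()  # margin +4.3
        c = classify(scores_1dp, patient, priors={"positive": 1e-3, "negative": 0.999})
        assert c.predicted == "negative"


class TestLikelihoodProduct:
    def test_worked_example_exact_product(self, retro_table):
        patient = WORKED_EXAMPLE_PATIENT.validated()
        expected = (
            Fraction(144, 197) * Fraction(111, 197) * Fraction(35, 197)
            * Fraction(136, 197) * Fraction(184, 197) * Fraction(57, 197)
        )
        assert likelihood_product(retro_table, patient, "positive") == expected

    def test_zero_frequency_level_gives_zero(self, toy_records):
        table = tabulate(Cohort.from_records(toy_records))
        rec = record_from_profile(("male", "lt45", "lt0.7", "absence", "absence", "upper"))
        assert likelihood_product(table, rec, "positive") == 0


class TestOracleEquivalence:
    def test_full_precision_agrees_with_rational_argmax(self, retro_table, scores_full):
        """Exhaustive: the score rule equals the likelihood rule on all 320
        profiles, ties included."""
        for profile in enumerate_profiles():
            rec = record_from_profile(profile)
            lp = likelihood_product(retro_table, rec, "positive")
            ln = likelihood_product(retro_table, rec, "negative")
            c = classify(scores_full, rec)
            oracle = "positive" if lp >= ln else "negative"
            assert c.predicted == oracle, profile
            assert c.tie == (lp == ln), profile

    def test_rounding_disagreements_only_in_perturbation_band(
        self, retro_table, scores_1dp, scores_full
    ):
        """Printed-table rounding can only flip decisions within the maximal
        rounding perturbation of six summed cells (6 × 0.05 per class)."""
        for profile in enumerate_profiles():
            rec = record_from_profile(profile)
            rounded = classify(scores_1dp, rec)
            full = classify(scores_full, rec)
            if rounded.predicted != full.predicted:
                assert abs(full.s_positive - full.s_negative) < 0.6, profile


class TestSklearnCrossCheck:
    def test_agrees_with_categorical_naive_bayes(self, retro_table):
        """Independent route: sklearn's categorical naive Bayes with uniform
        priors and vanishing smoothing reproduces the likelihood decision."""
        sklearn = pytest.importorskip("sklearn.naive_bayes")
        table_params = default_params(retro_table, n=3000, seed=11)
        cohort = generate_cohort(table_params)
        freq = tabulate(cohort)
        scores = derive_score_table(freq, rounding_mode=FULL_PRECISION, smoothing=1e-9)

        level_index = {
            factor: {lvl: i for i, lvl in enumerate(LEVELS[factor])} for factor in FACTORS
        }
        X = np.array(
            [[level_index[f][r.level(f)] for f in FACTORS] for r in cohort]
        )
        y = np.array([r.nodal_status for r in cohort])
        clf = sklearn.CategoricalNB(
            alpha=1e-9, fit_prior=False, min_categories=[2, 2, 5, 2, 2, 4]
        )
        clf.fit(X, y)

        profiles = enumerate_profiles()
        Xp = np.array(
            [[level_index[f][lvl] for f, lvl in zip(FACTORS, p)] for p in profiles]
        )
        sk_pred = clf.predict(Xp)
        for profile, sk in zip(profiles, sk_pred):
            c = classify(scores, record_from_profile(profile))
            if not c.tie and abs(c.s_positive - c.s_negative) > 1e-9:
                assert c.predicted == sk, profile
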