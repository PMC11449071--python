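import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from frailtraj.claims_core import FRAILTY_INDICATORS
from frailtraj.frailty_index import (
    FrailtyModel,
    IndicatorVector,
    apply_sensitivity,
    extract_indicators,
    indicator_prevalence,
    linear_predictor,
    score,
    score_series,
)

PERSON = pd.Series({
    "person_id": "P1", "birth_year": 1940, "sex": "F",
    "race_ethnicity": "White", "region": "West", "death_date": pd.NaT,
})
ANCHOR = pd.Timestamp("2010-06-01")


def claims_at(*entries):
    return pd.DataFrame({
        "person_id": [e[0] for e in entries],
        "service_date": pd.to_datetime([e[1] for e in entries]),
        "code": [e[2] for e in entries],
        "code_system": "SYN",
    })


@pytest.mark.parametrize(
    "offset,expected_flag",
    [(10, 1), (180, 1), (181, 0), (0, 0)],
)
def test_indicator_window_boundaries(offset, expected_flag):
    cl = claims_at(("P1", ANCHOR - pd.Timedelta(days=offset), "wheelchair"))
    iv = extract_indicators(cl, PERSON, ANCHOR)
    assert iv.flags["wheelchair"] == expected_flag


def test_indicators_are_binary_not_counts():
    cl = claims_at(
        ("P1", "2010-05-01", "wheelchair"), ("P1", "2010-05-20", "wheelchair")
    )
    iv = extract_indicators(cl, PERSON, ANCHOR)
    assert iv.flags["wheelchair"] == 1
    assert sum(iv.flags.values()) == 1


def zero_model(**kw):
    return FrailtyModel(
        intercept=0.0, age_coefficient=0.0,
        race_terms={r: 0.0 for r in ["White", "Black", "Hispanic", "API", "AI/AN", "missing"]},
        indicator_coefficients={i: 0.0 for i in FRAILTY_INDICATORS}, **kw,
    )


def iv_with(flags=None, age=70, race="White"):
    f = {i: 0 for i in FRAILTY_INDICATORS}
    f.update(flags or {})
    return IndicatorVector("P1", ANCHOR, f, age, race)


def test_all_zero_coefficients_give_half():
    assert score(zero_model(), iv_with()).score == pytest.approx(0.5)


def test_linear_predictor_minus_three():
    m = zero_model()
    m = FrailtyModel(**{**m.__dict__, "intercept": -3.0})
    s = score(m, iv_with())
    assert s.score == pytest.approx(1.0 / (1.0 + np.exp(3.0)), abs=1e-10)
    assert s.score == pytest.approx(0.04743, abs=1e-5)


def test_positive_flag_strictly_increases_score():
    m = FrailtyModel()
    s0 = score(m, iv_with()).score
    s1 = score(m, iv_with({"wheelchair": 1})).score
    assert s1 > s0
    # and a negatively weighted screening flag decreases it
    s2 = score(m, iv_with({"cancer_screening": 1})).score
    assert s2 < s0


def test_scores_in_open_unit_interval():
    m = FrailtyModel()
    all_on = iv_with({i: 1 for i in FRAILTY_INDICATORS}, age=95)
    assert 0 < score(m, iv_with(age=65)).score < 1
    assert 0 < score(m, all_on).score < 1


def test_unknown_race_falls_back_to_reference():
    m = FrailtyModel()
    assert linear_predictor(m, iv_with(race="unknown-cat")) == pytest.approx(
        linear_predictor(m, iv_with(race="White"))
    )


class TestSensitivity:
    def test_remove_nothing_is_identity(self):
        m = FrailtyModel()
        m2 = apply_sensitivity(m, [])
        assert m2.indicator_coefficients == m.indicator_coefficients

    def test_zero_flag_invariance(self):
        m = FrailtyModel()
        m2 = apply_sensitivity(m, ["cancer_screening", "lipid_abnormality"])
        iv = iv_with()  # both flags 0
        assert score(m2, iv).score == pytest.approx(score(m, iv).score)

    def test_removing_negative_indicator_raises_score(self):
        m = FrailtyModel()
        iv = iv_with({"cancer_screening": 1})
        assert score(apply_sensitivity(m, ["cancer_screening"]), iv).score > score(m, iv).score

    def test_idempotent(self):
        m = FrailtyModel()
        once = apply_sensitivity(m, ["cancer_screening"])
        twice = apply_sensitivity(once, ["cancer_screening"])
        assert once.indicator_coefficients == twice.indicator_coefficients
        assert once.model_id == twice.model_id

    def test_unknown_indicator_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            apply_sensitivity(FrailtyModel(), ["not_an_indicator"])


def one_person_tables(death=None, enroll_end="2012-12-31"):
    person = PERSON.copy()
    person["death_date"] = pd.Timestamp(death) if death else pd.NaT
    persons = pd.DataFrame([person])
    enrollment = pd.DataFrame({
        "person_id": ["P1"],
        "start_date": [pd.Timestamp("2009-01-01")],
        "end_date": [pd.Timestamp(enroll_end)],
        "coverage": ["FFS"],
    })
    return person, persons, enrollment


class TestScoreSeries:
    T0 = pd.Timestamp("2010-06-01")

    def test_full_followup_gives_13_scores(self):
        person, _, enrollment = one_person_tables()
        s = score_series(claims_at(("P1", "2010-05-01", "vertigo")), person,
                         self.T0, enrollment)
        assert len(s) == 13
        assert [x.anchor for x in s] == [
            self.T0 + pd.Timedelta(days=30 * m) for m in range(13)
        ]

    def test_death_truncates_series(self):
        person, _, enrollment = one_person_tables(
            death=self.T0 + pd.Timedelta(days=100)
        )
        s = score_series(claims_at(("P1", "2010-05-01", "vertigo")), person,
                         self.T0, enrollment)
        assert len(s) == 4  # days 0, 30, 60, 90 only

    def test_disenrollment_truncates_series(self):
        person, _, enrollment = one_person_tables(
            enroll_end=self.T0 + pd.Timedelta(days=70)
        )
        s = score_series(claims_at(("P1", "2010-05-01", "vertigo")), person,
                         self.T0, enrollment)
        assert len(s) == 3  # days 0, 30, 60

    def test_no_claims_gives_demographic_only_series(self):
        """With no claims every anchor scores at the demographic-only value
        (constant except for the age step at the calendar year boundary)."""
        person, _, enrollment = one_person_tables()
        empty = claims_at(("OTHER", "2010-05-01", "vertigo"))
        s = score_series(empty, person, self.T0, enrollment)
        m = FrailtyModel()
        for x in s:
            age = x.anchor.year - person["birth_year"]
            assert x.score == pytest.approx(score(m, iv_with(age=age)).score)
        assert len({round(x.score, 12) for x in s}) <= 2

    def test_no_lookahead(self):
        """Claims after an anchor never change the score at that anchor."""
        person, _, enrollment = one_person_tables()
        cl1 = claims_at(("P1", "2010-05-01", "wheelchair"))
        cl2 = claims_at(
            ("P1", "2010-05-01", "wheelchair"), ("P1", "2011-01-15", "dementia")
        )
        s1 = score_series(cl1, person, self.T0, enrollment)
        s2 = score_series(cl2, person, self.T0, enrollment)
        # anchors up to 2011-01-15 unchanged
        for a, b in zip(s1, s2):
            if b.anchor <= pd.Timestamp("2011-01-15"):
                assert a.score == pytest.approx(b.score)

    def test_duplication_and_order_invariance(self):
        person, _, enrollment = one_person_tables()
        cl = claims_at(
            ("P1", "2010-05-01", "wheelchair"), ("P1", "2010-04-01", "dementia")
        )
        shuffled = pd.concat([cl.iloc[::-1], cl]).reset_index(drop=True)
        s1 = score_series(cl, person, self.T0, enrollment)
        s2 = score_series(shuffled, person, self.T0, enrollment)
        assert [x.score for x in s1] == pytest.approx([x.score for x in s2])


def test_prevalence_binomial_oracle():
    """Constant claim probability 0.3 recovers prevalence 0.30 within 3 SE."""
    rng = np.random.default_rng(12)
    n = 5000
    ids = [f"Q{i}" for i in range(n)]
    has = rng.random(n) < 0.3
    claims = pd.DataFrame({
        "person_id": np.array(ids)[has],
        "service_date": pd.Timestamp("2010-05-01"),
        "code": "wheelchair", "code_system": "SYN",
    })
    persons = pd.DataFrame({
        "person_id": ids, "birth_year": 1940, "sex": "F",
        "race_ethnicity": "White", "region": "West", "death_date": pd.NaT,
    })
    enrollment = pd.DataFrame({
        "person_id": ids, "start_date": pd.Timestamp("2009-01-01"),
        "end_date": pd.Timestamp("2011-12-31"), "coverage": "FFS",
    })
    cohort = pd.DataFrame({
        "person_id": ids, "index_date": pd.Timestamp("2010-06-01"),
    })
    prev = indicator_prevalence(cohort, {"T1": 0}, claims, persons, enrollment)
    se = np.sqrt(0.3 * 0.7 / n)
    assert abs(prev.loc["wheelchair", "T1"] - 0.30) < 3 * se
    # indicator with no mapped claims is reported as zero
    assert prev.loc["dementia", "T1"] == 0.0


def test_prevalence_all_flagged():
    persons = pd.DataFrame({
        "person_id": ["A", "B"], "birth_year": 1940, "sex": "F",
        "race_ethnicity": "White", "region": "West", "death_date": pd.NaT,
    })
    enrollment = pd.DataFrame({
        "person_id": ["A", "B"], "start_date": pd.Timestamp("2009-01-01"),
        "end_date": pd.Timestamp("2011-12-31"), "coverage": "FFS",
    })
    claims = claims_at(("A", "2010-05-01", "wheelchair"), ("B", "2010-05-02", "wheelchair"))
    cohort = pd.DataFrame({"person_id": ["A", "B"], "index_date": pd.Timestamp("2010-06-01")})
    prev = indicator_prevalence(cohort, {"T1": 0}, claims, persons, enrollment)
    assert prev.loc["wheelchair", "T1"] == 1.0
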