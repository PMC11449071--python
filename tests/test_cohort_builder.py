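import numpy as np
import pandas as pd
import pytest

from frailtraj.claims_core import TableBundle, validate_bundle
from frailtraj.cohort_builder import (
    build_chemo_cohort,
    flu_vaccine_flag,
    gagne_score,
    match_comparators,
    screened_subset,
)

DX = pd.Timestamp("2010-01-10")


def make_bundle(surgery_lag=40, chemo_lag=40, neoadjuvant=False, stage="II",
                enroll_start="2009-01-01", extra_persons=()):
    surgery = DX + pd.Timedelta(days=surgery_lag)
    chemo = surgery + pd.Timedelta(days=chemo_lag)
    persons = [{
        "person_id": "CASE", "birth_year": 1940, "sex": "F",
        "race_ethnicity": "White", "region": "West", "death_date": pd.NaT,
    }]
    enrollment = [{
        "person_id": "CASE", "start_date": pd.Timestamp(enroll_start),
        "end_date": pd.Timestamp("2013-12-31"), "coverage": "FFS",
    }]
    for pid, by, region in extra_persons:
        persons.append({
            "person_id": pid, "birth_year": by, "sex": "F",
            "race_ethnicity": "Black", "region": region, "death_date": pd.NaT,
        })
        enrollment.append({
            "person_id": pid, "start_date": pd.Timestamp("2005-01-01"),
            "end_date": pd.Timestamp("2015-12-31"), "coverage": "FFS",
        })
    cancer = pd.DataFrame([{
        "person_id": "CASE", "diagnosis_date": DX, "stage": stage,
        "grade": "moderate", "surgery_date": surgery, "surgery_type": "BCT",
        "chemo_start_date": chemo, "neoadjuvant_flag": neoadjuvant,
    }])
    claims = pd.DataFrame(columns=["person_id", "service_date", "code", "code_system"])
    claims["service_date"] = pd.to_datetime(claims["service_date"])
    return validate_bundle(TableBundle(
        pd.DataFrame(persons), pd.DataFrame(enrollment), claims, cancer
    ))


@pytest.mark.parametrize(
    "kw,retained,failing_step",
    [
        ({"surgery_lag": 90}, True, None),
        ({"surgery_lag": 91}, False, "surgery within 90d of diagnosis"),
        ({"chemo_lag": 90}, True, None),
        ({"chemo_lag": 91}, False, "adjuvant chemo within 90d of surgery"),
        ({"neoadjuvant": True}, False, "no neoadjuvant chemotherapy"),
        ({"stage": "other"}, False, "stage I-III"),
        # enrollment starting after diagnosis breaks the continuity rule
        ({"enroll_start": "2010-02-01"}, False, "continuous FFS enrollment"),
    ],
)
def test_eligibility_chain_boundaries(kw, retained, failing_step):
    cohort, ledger = build_chemo_cohort(make_bundle(**kw))
    assert (len(cohort) == 1) == retained
    if failing_step:
        row = ledger[ledger["criterion"] == failing_step]
        assert row["n_removed"].iloc[0] == 1


def test_ledger_counts_are_consistent():
    cohort, ledger = build_chemo_cohort(make_bundle())
    assert (ledger["n_remaining"].diff().dropna() <= 0).all()
    assert ledger["n_remaining"].iloc[-1] == len(cohort)
    assert cohort["index_date"].iloc[0] == DX + pd.Timedelta(days=80)


class TestMatching:
    def bundle_with_pool(self, n_pool, birth_year=1940, region="West"):
        extras = [(f"N{i}", birth_year, region) for i in range(n_pool)]
        return make_bundle(extra_persons=extras)

    def test_up_to_five_from_large_stratum(self):
        b = self.bundle_with_pool(7)
        chemo, _ = build_chemo_cohort(b)
        out = match_comparators(chemo, b, ratio=5, seed=1)
        comp = out[out["arm"] == "comparator"]
        assert len(comp) == 5
        assert comp["person_id"].nunique() == 5  # no duplicates within a group

    def test_small_stratum_gives_all(self):
        b = self.bundle_with_pool(2)
        chemo, _ = build_chemo_cohort(b)
        out = match_comparators(chemo, b, ratio=5, seed=1)
        assert (out["arm"] == "comparator").sum() == 2

    def test_no_eligible_comparators_keeps_case(self):
        b = self.bundle_with_pool(3, birth_year=1930)  # wrong stratum
        chemo, _ = build_chemo_cohort(b)
        out = match_comparators(chemo, b, ratio=5, seed=1)
        assert (out["arm"] == "chemo").sum() == 1
        assert (out["arm"] == "comparator").sum() == 0
        assert out.attrs["n_unmatched"] == 1

    def test_exact_key_equality_and_inherited_index(self, small_bundle):
        chemo, _ = build_chemo_cohort(small_bundle)
        out = match_comparators(chemo, small_bundle, ratio=5, seed=3)
        comp = out[out["arm"] == "comparator"]
        chemo_rows = out[out["arm"] == "chemo"].set_index("person_id")
        by = small_bundle.persons.set_index("person_id")["birth_year"]
        for _, r in comp.iterrows():
            case = chemo_rows.loc[r["match_group"]]
            assert r["index_date"] == case["index_date"]
            assert r["region"] == case["region"]
            case_by = case["index_date"].year - case["age"]
            assert by[r["person_id"]] == case_by

    def test_replacement_across_groups(self, small_bundle):
        chemo, _ = build_chemo_cohort(small_bundle)
        out = match_comparators(chemo, small_bundle, ratio=5, seed=3)
        comp = out[out["arm"] == "comparator"]
        # with a 5x pool and exact strata, at least one pool person serves
        # several cases (sampling is with replacement across groups)
        assert comp["person_id"].duplicated().any()

    def test_same_seed_reproducible(self, small_bundle):
        chemo, _ = build_chemo_cohort(small_bundle)
        a = match_comparators(chemo, small_bundle, ratio=5, seed=9)
        b = match_comparators(chemo, small_bundle, ratio=5, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_ratio_below_one_rejected(self, small_bundle):
        chemo, _ = build_chemo_cohort(small_bundle)
        with pytest.raises(ValueError, match="ratio"):
            match_comparators(chemo, small_bundle, ratio=0, seed=1)


class TestCovariates:
    person = pd.Series({"person_id": "CASE"})
    anchor = pd.Timestamp("2010-06-01")

    def claims(self, *entries):
        return pd.DataFrame({
            "person_id": "CASE",
            "service_date": pd.to_datetime([e[0] for e in entries]),
            "code": [e[1] for e in entries],
            "code_system": "SYN",
        })

    def test_no_claims_scores_zero(self):
        assert gagne_score(self.claims(), self.person, self.anchor) == 0.0

    def test_single_weight_two_condition(self):
        cl = self.claims(("2010-05-01", "congestive_heart_failure"))
        assert gagne_score(cl, self.person, self.anchor) == 2.0

    def test_additivity_and_negative_weight(self):
        cl = self.claims(
            ("2010-05-01", "congestive_heart_failure"),
            ("2010-04-01", "cardiac_arrhythmia"),
            ("2010-03-15", "hypertension_uncomplicated"),
        )
        assert gagne_score(cl, self.person, self.anchor) == 2.0 + 1.0 - 1.0

    def test_cancer_conditions_excluded(self):
        cl = self.claims(
            ("2010-05-01", "cancer_nonmetastatic"), ("2010-05-02", "metastatic_cancer")
        )
        assert gagne_score(cl, self.person, self.anchor) == 0.0

    def test_out_of_window_condition_ignored(self):
        cl = self.claims(("2009-05-01", "congestive_heart_failure"))
        assert gagne_score(cl, self.person, self.anchor) == 0.0

    def test_missing_weight_is_error(self):
        cl = self.claims(("2010-05-01", "congestive_heart_failure"))
        with pytest.raises(ValueError, match="no weight"):
            gagne_score(cl, self.person, self.anchor,
                        gagne_weights={"cardiac_arrhythmia": 1})

    @pytest.mark.parametrize("offset,expected", [(30, True), (200, False), (0, False)])
    def test_flu_vaccine_window(self, offset, expected):
        cl = self.claims((self.anchor - pd.Timedelta(days=offset), "flu_vaccine"))
        assert flu_vaccine_flag(cl, self.person, self.anchor) == expected


class TestScreenedSubset:
    def with_claims(self, bundle, entries):
        rows = pd.DataFrame({
            "person_id": [e[0] for e in entries],
            "service_date": pd.to_datetime([e[1] for e in entries]),
            "code": [e[2] for e in entries],
            "code_system": "SYN",
        })
        bundle.claims = pd.concat([bundle.claims, rows], ignore_index=True)
        return bundle

    def test_chemo_mammogram_window(self):
        for lag, kept in [(100, True), (400, False)]:
            b = make_bundle()
            b = self.with_claims(b, [("CASE", DX - pd.Timedelta(days=lag), "mammogram")])
            cohort, _ = build_chemo_cohort(b)
            out = screened_subset(cohort, b)
            assert (len(out) == 1) == kept

    def test_comparator_with_cancer_record_dropped(self):
        b = make_bundle(extra_persons=[("N0", 1940, "West")])
        idx = DX + pd.Timedelta(days=80)
        b = self.with_claims(b, [
            ("CASE", DX - pd.Timedelta(days=100), "mammogram"),
            ("N0", idx - pd.Timedelta(days=100), "mammogram"),
        ])
        chemo, _ = build_chemo_cohort(b)
        cohort = match_comparators(chemo, b, seed=0)
        assert (cohort["arm"] == "comparator").sum() == 1
        out = screened_subset(cohort, b)
        assert set(out["arm"]) == {"chemo", "comparator"}
        # now give the comparator a cancer record: she must drop out
        b.cancer = pd.concat([b.cancer, pd.DataFrame([{
            "person_id": "N0", "diagnosis_date": idx + pd.Timedelta(days=200),
            "stage": "I", "grade": "well", "surgery_date": pd.NaT,
            "surgery_type": "none", "chemo_start_date": pd.NaT,
            "neoadjuvant_flag": False,
        }])], ignore_index=True)
        out2 = screened_subset(cohort, b)
        assert set(out2["arm"]) == {"chemo"}
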