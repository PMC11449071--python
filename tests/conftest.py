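import numpy as np
import pandas as pd
import pytest

from frailtraj.synthetic_data import SimConfig, generate_population


@pytest.fixture(scope="session")
def small_sim():
    """Small but complete synthetic study (shared, read-only)."""
    config = SimConfig(n_chemo=150, seed=20240501)
    bundle, truth = generate_population(config)
    return config, bundle, truth


@pytest.fixture(scope="session")
def small_bundle(small_sim):
    return small_sim[1]


@pytest.fixture()
def tiny_bundle():
    """Three-person hand-written bundle for schema/invariant tests."""
    from frailtraj.claims_core import TableBundle, validate_bundle

    persons = pd.DataFrame({
        "person_id": ["A", "B", "C"],
        "birth_year": [1935, 1940, 1938],
        "sex": ["F"] * 3,
        "race_ethnicity": ["White", "Black", "Hispanic"],
        "region": ["West", "South", "Northeast"],
        "death_date": [pd.NaT, pd.Timestamp("2012-06-30"), pd.NaT],
    })
    enrollment = pd.DataFrame({
        "person_id": ["A", "B", "C"],
        "start_date": pd.to_datetime(["2005-01-01"] * 3),
        "end_date": pd.to_datetime(["2015-12-31", "2012-06-30", "2015-12-31"]),
        "coverage": ["FFS"] * 3,
    })
    claims = pd.DataFrame({
        "person_id": ["A", "A", "B"],
        "service_date": pd.to_datetime(["2010-03-01", "2010-05-10", "2011-01-15"]),
        "code": ["wheelchair", "cancer_screening", "heart_failure"],
        "code_system": ["SYN"] * 3,
    })
    cancer = pd.DataFrame({
        "person_id": ["A"],
        "diagnosis_date": [pd.Timestamp("2010-01-10")],
        "stage": ["II"],
        "grade": ["moderate"],
        "surgery_date": [pd.Timestamp("2010-02-15")],
        "surgery_type": ["BCT"],
        "chemo_start_date": [pd.Timestamp("2010-04-01")],
        "neoadjuvant_flag": [False],
    })
    bundle = TableBundle(persons, enrollment, claims, cancer)
    return validate_bundle(bundle)
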