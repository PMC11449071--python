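"""Study cohorts: eligibility chain, matched comparators, covariates.

The chemotherapy cohort applies the eligibility rules of the emulated
study: women 65+ with stage I-III disease, primary surgery within 90 days
of diagnosis, adjuvant chemotherapy within 90 days of surgery (the index
date), no neoadjuvant treatment, and continuous fee-for-service enrollment
from diagnosis to index or for 180 days pre-index, whichever is longer.
Each exclusion step is recorded in an ordered ledger (consort-diagram
shape).

Comparators are drawn from the noncancer pool by exact matching on year of
birth and region, up to five per case, randomly with replacement across
match groups (never twice within one group); they inherit the case's index
date and must satisfy the same enrollment rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .claims_core import (
    DEFAULT_GAGNE_WEIGHTS,
    DEFAULT_LOOKBACK_DAYS,
    GAGNE_CONDITIONS,
    GAGNE_EXCLUDED_CONDITIONS,
    CodeMap,
    TableBundle,
    in_window,
)

GAGNE_CATEGORIES = ["<0", "0", "1", "2", "3+"]


def gagne_category(score: float) -> str:
    if score < 0:
        return "<0"
    if score >= 3:
        return "3+"
    return str(int(score))


def _merged_ffs_intervals(enrollment: pd.DataFrame) -> dict:
    """person_id -> list of merged (start, end) FFS coverage intervals."""
    ffs = enrollment[enrollment["coverage"] == "FFS"].sort_values(
        ["person_id", "start_date"]
    )
    out: dict = {}
    one_day = pd.Timedelta(days=1)
    for pid, g in ffs.groupby("person_id"):
        merged = []
        for s, e in zip(g["start_date"], g["end_date"]):
            if merged and s <= merged[-1][1] + one_day:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        out[pid] = merged
    return out


def _covers(intervals: list, start, end) -> bool:
    for s, e in intervals:
        if s <= start and e >= end:
            return True
    return False


def enrollment_rule_window(diagnosis_date, index_date) -> pd.Timestamp:
    """Start of the required continuous-enrollment interval: diagnosis or
    index - 180 days, whichever is earlier (the longer requirement)."""
    fallback = index_date - pd.Timedelta(days=DEFAULT_LOOKBACK_DAYS)
    if diagnosis_date is None or pd.isna(diagnosis_date):
        return fallback
    return min(diagnosis_date, fallback)


def build_chemo_cohort(
    bundle: TableBundle,
    min_age: int = 65,
    surgery_window_days: int = 90,
    chemo_window_days: int = 90,
    codemap: CodeMap | None = None,
    gagne_weights: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the eligibility chain; returns (cohort, exclusion ledger).

    Timing windows are closed ([0, 90] days).  The ledger rows record each
    criterion in the order applied with counts removed and remaining.
    """
    cancer = bundle.cancer.merge(bundle.persons, on="person_id", how="inner")
    ledger = []
    n0 = len(cancer)
    ledger.append(("cancer diagnosis", 0, n0))

    def step(mask: pd.Series, name: str, df: pd.DataFrame) -> pd.DataFrame:
        kept = df.loc[np.asarray(mask, dtype=bool)]
        ledger.append((name, len(df) - len(kept), len(kept)))
        return kept

    df = cancer
    age_dx = df["diagnosis_date"].dt.year - df["birth_year"]
    df = step(age_dx >= min_age, f"age >= {min_age} at diagnosis", df)
    df = step(df["stage"].isin(["I", "II", "III"]), "stage I-III", df)
    surg_ok = (
        df["surgery_date"].notna()
        & (df["surgery_type"] != "none")
        & ((df["surgery_date"] - df["diagnosis_date"]).dt.days >= 0)
        & ((df["surgery_date"] - df["diagnosis_date"]).dt.days <= surgery_window_days)
    )
    df = step(surg_ok, f"surgery within {surgery_window_days}d of diagnosis", df)
    chemo_ok = (
        df["chemo_start_date"].notna()
        & ((df["chemo_start_date"] - df["surgery_date"]).dt.days >= 0)
        & ((df["chemo_start_date"] - df["surgery_date"]).dt.days <= chemo_window_days)
    )
    df = step(chemo_ok, f"adjuvant chemo within {chemo_window_days}d of surgery", df)
    df = step(~df["neoadjuvant_flag"], "no neoadjuvant chemotherapy", df)

    intervals = _merged_ffs_intervals(bundle.enrollment)
    enroll_ok = []
    for pid, dx, idx in zip(df["person_id"], df["diagnosis_date"], df["chemo_start_date"]):
        start = enrollment_rule_window(dx, idx)
        enroll_ok.append(_covers(intervals.get(pid, []), start, idx))
    df = step(pd.Series(enroll_ok, index=df.index), "continuous FFS enrollment", df)

    cohort = pd.DataFrame({
        "person_id": df["person_id"].to_numpy(),
        "arm": "chemo",
        "index_date": df["chemo_start_date"].to_numpy(),
        "match_group": df["person_id"].to_numpy(),
        "age": (pd.DatetimeIndex(df["chemo_start_date"]).year - df["birth_year"]).to_numpy(),
        "race_ethnicity": df["race_ethnicity"].to_numpy(),
        "region": df["region"].to_numpy(),
        "stage": df["stage"].to_numpy(),
        "grade": df["grade"].to_numpy(),
        "surgery_type": df["surgery_type"].to_numpy(),
        "diagnosis_date": df["diagnosis_date"].to_numpy(),
    })
    cohort = add_baseline_covariates(cohort, bundle, codemap, gagne_weights)
    ledger_df = pd.DataFrame(ledger, columns=["criterion", "n_removed", "n_remaining"])
    return cohort.reset_index(drop=True), ledger_df


def match_comparators(
    chemo_cohort: pd.DataFrame,
    bundle: TableBundle,
    ratio: int = 5,
    seed: int = 0,
    codemap: CodeMap | None = None,
    gagne_weights: dict | None = None,
) -> pd.DataFrame:
    """Exact matching on (birth_year, region), up to ``ratio`` comparators
    per case, sampled uniformly without duplication within a match group and
    with replacement across groups.

    Comparators inherit the case's index date and must be continuously
    FFS-enrolled for the 180 days up to it.  Cases with no eligible
    comparator keep their chemo row (``n_unmatched`` in ``attrs``).
    Deterministic for a fixed seed.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    rng = np.random.default_rng(seed)
    persons = bundle.persons
    pool = persons[
        ~persons["person_id"].isin(bundle.cancer["person_id"])
        & ~persons["person_id"].isin(chemo_cohort["person_id"])
    ]
    intervals = _merged_ffs_intervals(
        bundle.enrollment[bundle.enrollment["person_id"].isin(pool["person_id"])]
    )
    strata: dict = {
        key: g["person_id"].to_numpy()
        for key, g in pool.groupby(["birth_year", "region"], observed=True)
    }
    pinfo = persons.set_index("person_id")

    rows = []
    n_unmatched = 0
    cases = chemo_cohort.sort_values("person_id")
    case_birth_year = (
        pd.DatetimeIndex(cases["index_date"]).year.to_numpy() - cases["age"].to_numpy()
    )
    for (_, case), by in zip(cases.iterrows(), case_birth_year):
        key = (by, case["region"])
        candidates = strata.get(key, np.array([], dtype=object))
        idx = pd.Timestamp(case["index_date"])
        start = idx - pd.Timedelta(days=DEFAULT_LOOKBACK_DAYS)
        eligible = [
            pid for pid in candidates if _covers(intervals.get(pid, []), start, idx)
        ]
        if not eligible:
            n_unmatched += 1
            continue
        k = min(ratio, len(eligible))
        chosen = rng.choice(np.array(eligible, dtype=object), size=k, replace=False)
        for pid in chosen:
            p = pinfo.loc[pid]
            rows.append({
                "person_id": pid,
                "arm": "comparator",
                "index_date": idx,
                "match_group": case["person_id"],
                "age": idx.year - int(p["birth_year"]),
                "race_ethnicity": p["race_ethnicity"],
                "region": p["region"],
                "stage": pd.NA,
                "grade": pd.NA,
                "surgery_type": pd.NA,
                "diagnosis_date": pd.NaT,
            })
    comp = pd.DataFrame(rows)
    if len(comp):
        comp = add_baseline_covariates(comp, bundle, codemap, gagne_weights)
    out = pd.concat([chemo_cohort, comp], ignore_index=True)
    out["row_id"] = np.arange(len(out))
    out.attrs["n_unmatched"] = n_unmatched
    return out


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def _condition_flags(
    claims: pd.DataFrame,
    anchor_frame: pd.DataFrame,
    conditions: list[str],
    lookback_days: int,
    codemap: CodeMap,
) -> pd.DataFrame:
    cl = claims.copy()
    cl["indicator"] = codemap.translate(cl)
    cl = cl[cl["indicator"].isin(conditions)]
    out = pd.DataFrame(
        0, index=pd.Index(anchor_frame["row_id"], name="row_id"),
        columns=conditions, dtype="int8",
    )
    merged = anchor_frame[["row_id", "person_id", "anchor"]].merge(
        cl[["person_id", "service_date", "indicator"]], on="person_id", how="inner"
    )
    lo = merged["anchor"] - pd.Timedelta(days=lookback_days)
    hit = merged[(merged["service_date"] >= lo) & (merged["service_date"] < merged["anchor"])]
    if len(hit):
        flags = (
            hit.groupby(["row_id", "indicator"]).size().unstack(fill_value=0) > 0
        ).astype("int8")
        out.loc[flags.index, flags.columns] = flags
    return out


def gagne_frame(
    claims: pd.DataFrame,
    anchor_frame: pd.DataFrame,
    gagne_weights: dict | None = None,
    excluded: list[str] | None = None,
    lookback_days: int = DEFAULT_LOOKBACK_DAYS,
    codemap: CodeMap | None = None,
) -> pd.Series:
    """Comorbidity score per anchor row: weighted sum of condition flags in
    the 180-day window, cancer conditions excluded."""
    weights = dict(DEFAULT_GAGNE_WEIGHTS if gagne_weights is None else gagne_weights)
    excluded = GAGNE_EXCLUDED_CONDITIONS if excluded is None else list(excluded)
    codemap = codemap or CodeMap.synthetic_identity()
    mapped = set(codemap.mapping.values()) & set(GAGNE_CONDITIONS)
    missing = sorted(c for c in mapped if c not in weights and c not in excluded)
    if missing:
        raise ValueError(f"no weight for conditions: {missing}")
    conditions = [c for c in weights if c not in excluded]
    flags = _condition_flags(claims, anchor_frame, conditions, lookback_days, codemap)
    w = np.array([weights[c] for c in conditions], dtype=float)
    return pd.Series(flags.to_numpy() @ w, index=flags.index, name="gagne_score")


def gagne_score(
    claims: pd.DataFrame,
    person: pd.Series,
    anchor,
    gagne_weights: dict | None = None,
    excluded: list[str] | None = None,
    lookback_days: int = DEFAULT_LOOKBACK_DAYS,
    codemap: CodeMap | None = None,
) -> float:
    """Scalar comorbidity score for one person at one anchor."""
    af = pd.DataFrame({
        "row_id": [0],
        "person_id": [person["person_id"]],
        "anchor": [pd.Timestamp(anchor)],
    })
    return float(
        gagne_frame(claims, af, gagne_weights, excluded, lookback_days, codemap).iloc[0]
    )


def flu_vaccine_flag(
    claims: pd.DataFrame,
    person: pd.Series,
    index_date,
    lookback_days: int = DEFAULT_LOOKBACK_DAYS,
    codemap: CodeMap | None = None,
) -> bool:
    """Any flu-vaccine claim in the half-open 180-day window before index."""
    codemap = codemap or CodeMap.synthetic_identity()
    sub = claims[claims["person_id"] == person["person_id"]].copy()
    if not len(sub):
        return False
    ind = codemap.translate(sub)
    ok = in_window(sub["service_date"], index_date, lookback_days)
    return bool((np.asarray(ok) & (ind == "flu_vaccine").to_numpy()).any())


def add_baseline_covariates(
    cohort: pd.DataFrame,
    bundle: TableBundle,
    codemap: CodeMap | None = None,
    gagne_weights: dict | None = None,
) -> pd.DataFrame:
    """Attach baseline comorbidity score/category and flu-vaccine flag."""
    codemap = codemap or CodeMap.synthetic_identity()
    cohort = cohort.copy().reset_index(drop=True)
    af = pd.DataFrame({
        "row_id": np.arange(len(cohort)),
        "person_id": cohort["person_id"].to_numpy(),
        "anchor": pd.to_datetime(cohort["index_date"]).to_numpy(),
    })
    g = gagne_frame(bundle.claims, af, gagne_weights, codemap=codemap)
    cohort["gagne_score"] = g.to_numpy()
    cohort["gagne_category"] = [gagne_category(s) for s in cohort["gagne_score"]]
    flu = _condition_flags(bundle.claims, af, ["flu_vaccine"], DEFAULT_LOOKBACK_DAYS, codemap)
    cohort["flu_vaccine_flag"] = flu["flu_vaccine"].astype(bool).to_numpy()
    return cohort


def screened_subset(
    cohort: pd.DataFrame,
    bundle: TableBundle,
    codemap: CodeMap | None = None,
    lookback_days: int = 365,
) -> pd.DataFrame:
    """Restrict to the mammography-screened subpopulation.

    Chemo rows require a mammogram in the year before diagnosis; comparator
    rows require one in the year before the index date and no cancer record
    at any time.
    """
    codemap = codemap or CodeMap.synthetic_identity()
    cohort = cohort.copy().reset_index(drop=True)
    anchor = np.where(
        cohort["arm"].to_numpy() == "chemo",
        pd.to_datetime(cohort["diagnosis_date"]).to_numpy(),
        pd.to_datetime(cohort["index_date"]).to_numpy(),
    )
    af = pd.DataFrame({
        "row_id": np.arange(len(cohort)),
        "person_id": cohort["person_id"].to_numpy(),
        "anchor": anchor,
    })
    flags = _condition_flags(bundle.claims, af, ["mammogram"], lookback_days, codemap)
    keep = flags["mammogram"].to_numpy().astype(bool)
    has_cancer = cohort["person_id"].isin(bundle.cancer["person_id"]).to_numpy()
    keep &= (cohort["arm"].to_numpy() == "chemo") | ~has_cancer
    return cohort[keep].reset_index(drop=True)
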