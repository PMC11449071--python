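"""Shared domain model for administrative-claims analyses.

Tabular containers (persons, enrollment spells, claims, cancer records),
schema validation, CSV/Parquet round-tripping, and the two date conventions
every downstream stage must share:

* ``in_window`` — the half-open lookback window ``[anchor - L, anchor)``
  used for all claims ascertainment (frailty indicators, comorbidity
  scoring, flu vaccination).  The anchor day itself is excluded so that
  same-day treatment claims never leak into a baseline window.
* ``continuous_enrollment`` — gap-free fee-for-service coverage of an
  interval, the eligibility backbone of cohort construction.

"Month" throughout the package means a 30-day block, so 4 months after an
index date is day 120 and 12 months is day 360.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

DAYS_PER_MONTH = 30
DEFAULT_LOOKBACK_DAYS = 180

#: Benchmark-analysis timepoints: index date, 4 months and 10 months
#: post-index under the 30-day-month convention.
TIMEPOINT_OFFSETS = {"T1": 0, "T2": 120, "T3": 300}

RACE_CATEGORIES = ["White", "Black", "Hispanic", "API", "AI/AN", "missing"]
REGION_CATEGORIES = ["Northeast", "West", "Midwest", "South"]
COVERAGE_CATEGORIES = ["FFS", "HMO"]
CODE_SYSTEMS = ["ICD", "CPT", "HCPCS", "SYN"]
STAGE_CATEGORIES = ["I", "II", "III", "other"]
GRADE_CATEGORIES = ["well", "moderate", "poor", "undifferentiated", "missing"]
SURGERY_TYPES = ["mastectomy", "BCT", "none"]

#: The 20 binary components of the claims-based frailty index.  Two of them
#: (cancer screening, lipid abnormality) mark preventive/screening services
#: and carry protective (negative) coefficients; the rest mark deficits.
FRAILTY_INDICATORS = [
    "parkinson_disease",
    "home_hospital_bed",
    "wheelchair",
    "home_oxygen",
    "paralysis",
    "podiatric_care",
    "psychiatric_diagnoses",
    "dementia",
    "skin_ulcer_decubitus",
    "stroke_brain_injury",
    "ambulance_life_support",
    "bladder_dysfunction",
    "arthritis_joint_conditions",
    "vertigo",
    "heart_failure",
    "weakness",
    "lipid_abnormality",
    "rehabilitation_services",
    "cancer_screening",
    "hypotension_shock",
]

SCREENING_INDICATORS = ["cancer_screening", "lipid_abnormality"]

SERVICE_INDICATORS = ["surgery", "chemotherapy", "mammogram", "flu_vaccine"]

#: Comorbid conditions entering the combined (Charlson + Elixhauser style)
#: comorbidity score.  The weights shipped in DEFAULT_GAGNE_WEIGHTS are a
#: documented synthetic default in the spirit of the published combined
#: score (a few 2-point conditions, mostly 1-point, one negative weight so
#: that scores below zero occur); they are fully configurable.
GAGNE_CONDITIONS = [
    "congestive_heart_failure",
    "dementia_comorbid",
    "renal_failure",
    "weight_loss",
    "metastatic_cancer",
    "cancer_nonmetastatic",
    "cardiac_arrhythmia",
    "chronic_pulmonary_disease",
    "complicated_diabetes",
    "deficiency_anemia",
    "liver_disease",
    "peripheral_vascular_disease",
    "psychosis",
    "fluid_electrolyte_disorders",
    "hemiplegia",
    "hypertension_uncomplicated",
]

DEFAULT_GAGNE_WEIGHTS = {
    "congestive_heart_failure": 2,
    "dementia_comorbid": 2,
    "renal_failure": 2,
    "weight_loss": 2,
    "metastatic_cancer": 5,
    "cancer_nonmetastatic": 2,
    "cardiac_arrhythmia": 1,
    "chronic_pulmonary_disease": 1,
    "complicated_diabetes": 1,
    "deficiency_anemia": 1,
    "liver_disease": 1,
    "peripheral_vascular_disease": 1,
    "psychosis": 1,
    "fluid_electrolyte_disorders": 1,
    "hemiplegia": 1,
    "hypertension_uncomplicated": -1,
}

#: Conditions never counted toward the comorbidity score in this study
#: (cancer history is the exposure, not a comorbidity).
GAGNE_EXCLUDED_CONDITIONS = ["metastatic_cancer", "cancer_nonmetastatic"]

PERSON_COLUMNS = {
    "person_id": "string",
    "birth_year": "int64",
    "sex": "string",
    "race_ethnicity": "string",
    "region": "string",
    "death_date": "date",
}
ENROLLMENT_COLUMNS = {
    "person_id": "string",
    "start_date": "date",
    "end_date": "date",
    "coverage": "string",
}
CLAIM_COLUMNS = {
    "person_id": "string",
    "service_date": "date",
    "code": "string",
    "code_system": "string",
}
CANCER_COLUMNS = {
    "person_id": "string",
    "diagnosis_date": "date",
    "stage": "string",
    "grade": "string",
    "surgery_date": "date",
    "surgery_type": "string",
    "chemo_start_date": "date",
    "neoadjuvant_flag": "bool",
}

_TABLE_SCHEMAS = {
    "persons": PERSON_COLUMNS,
    "enrollment": ENROLLMENT_COLUMNS,
    "claims": CLAIM_COLUMNS,
    "cancer": CANCER_COLUMNS,
}


class SchemaError(ValueError):
    """A table does not conform to the declared schema."""


class ValidationError(ValueError):
    """A hard invariant of the data model is violated."""


@dataclass
class CodeMap:
    """Mapping from (code_system, code) to a named indicator.

    In synthetic mode claims carry abstract codes (``code_system == "SYN"``
    and ``code`` equal to the indicator name), so the identity map suffices.
    Real code lists (ICD/CPT/HCPCS) are user-supplied as YAML and are not
    shipped with the package.
    """

    mapping: dict[tuple[str, str], str] = field(default_factory=dict)
    #: indicators declared absent from the map on purpose
    declared_absent: set[str] = field(default_factory=set)

    @classmethod
    def synthetic_identity(cls) -> "CodeMap":
        """Identity map for abstract SYN codes covering all indicators."""
        names = FRAILTY_INDICATORS + SERVICE_INDICATORS + GAGNE_CONDITIONS
        return cls(mapping={("SYN", name): name for name in names})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CodeMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        mapping: dict[tuple[str, str], str] = {}
        absent: set[str] = set()
        for name, entry in (raw.get("indicators") or {}).items():
            if entry is None or entry.get("absent"):
                absent.add(name)
                continue
            system = entry["system"]
            for code in entry["codes"]:
                key = (str(system), str(code))
                if key in mapping and mapping[key] != name:
                    raise ValidationError(
                        f"code {key} mapped to both {mapping[key]!r} and {name!r}"
                    )
                mapping[key] = name
        cm = cls(mapping=mapping, declared_absent=absent)
        cm.check_frailty_coverage()
        return cm

    def check_frailty_coverage(self) -> None:
        covered = set(self.mapping.values()) | self.declared_absent
        missing = [i for i in FRAILTY_INDICATORS if i not in covered]
        if missing:
            raise ValidationError(
                "frailty indicators with no code pattern and not declared "
                f"absent: {missing}"
            )

    def translate(self, claims: pd.DataFrame) -> pd.Series:
        """Map each claim row to its indicator name (NaN when unmapped)."""
        keys = list(zip(claims["code_system"], claims["code"]))
        return pd.Series(
            [self.mapping.get(k, np.nan) for k in keys],
            index=claims.index,
            dtype="object",
        )


@dataclass
class TableBundle:
    """Validated collection of the four analysis input tables."""

    persons: pd.DataFrame
    enrollment: pd.DataFrame
    claims: pd.DataFrame
    cancer: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def copy(self) -> "TableBundle":
        return TableBundle(
            self.persons.copy(),
            self.enrollment.copy(),
            self.claims.copy(),
            self.cancer.copy(),
            list(self.warnings),
        )


def _coerce_table(df: pd.DataFrame, name: str) -> pd.DataFrame:
    schema = _TABLE_SCHEMAS[name]
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"table {name!r} missing columns {missing}")
    out = df.loc[:, list(schema)].copy()
    for col, kind in schema.items():
        if kind == "date":
            out[col] = pd.to_datetime(out[col], format="ISO8601", errors="raise")
        elif kind == "int64":
            out[col] = pd.to_numeric(out[col], errors="raise").astype("int64")
        elif kind == "bool":
            if out[col].dtype != bool:
                out[col] = (
                    out[col]
                    .astype("string")
                    .str.lower()
                    .map({"true": True, "false": False, "1": True, "0": False})
                    .astype(bool)
                )
        else:
            out[col] = out[col].astype("string")
    return out


def validate_bundle(
    bundle: TableBundle, death_slack_days: int = 0
) -> TableBundle:
    """Check the data-model invariants.

    Hard errors: duplicate person ids, inverted date pairs, overlapping
    enrollment spells within a coverage class, claims dated after death.
    Soft warning: claims falling outside every enrollment spell of their
    person (orphan claims).
    """
    warnings: list[str] = []
    persons, enroll, claims, cancer = (
        bundle.persons,
        bundle.enrollment,
        bundle.claims,
        bundle.cancer,
    )

    dup = persons["person_id"][persons["person_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate person_id values: {sorted(set(dup))[:5]}")

    bad = enroll[enroll["start_date"] > enroll["end_date"]]
    if len(bad):
        raise ValidationError(
            f"enrollment spells with start after end for {bad['person_id'].tolist()[:5]}"
        )
    # overlap check within (person, coverage)
    es = enroll.sort_values(["person_id", "coverage", "start_date"])
    same = (es["person_id"] == es["person_id"].shift()) & (
        es["coverage"] == es["coverage"].shift()
    )
    overlap = same & (es["start_date"] <= es["end_date"].shift())
    if overlap.any():
        who = es.loc[overlap, "person_id"].tolist()[:5]
        raise ValidationError(f"overlapping enrollment spells for {who}")

    if len(claims):
        death = persons.set_index("person_id")["death_date"]
        cd = claims["person_id"].map(death)
        late = claims["service_date"] > (cd + pd.Timedelta(days=death_slack_days))
        late = late.fillna(False)
        if late.any():
            who = sorted(set(claims.loc[late, "person_id"]))[:5]
            raise ValidationError(f"claims dated after death for person_id {who}")

        # orphan claims: outside every enrollment spell -> warning only
        merged = claims.reset_index().merge(enroll, on="person_id", how="left")
        inside = (merged["service_date"] >= merged["start_date"]) & (
            merged["service_date"] <= merged["end_date"]
        )
        covered = inside.groupby(merged["index"]).any()
        n_orphan = int((~covered).sum())
        if n_orphan:
            warnings.append(f"{n_orphan} claims outside any enrollment spell")

    if len(cancer):
        sd, dd, cs = (
            cancer["surgery_date"],
            cancer["diagnosis_date"],
            cancer["chemo_start_date"],
        )
        if ((sd.notna()) & (sd < dd)).any():
            raise ValidationError("surgery_date before diagnosis_date")
        if ((cs.notna()) & (sd.notna()) & (cs < sd)).any():
            raise ValidationError("chemo_start_date before surgery_date")

    bundle.warnings = warnings
    return bundle


def read_tables(
    paths: Mapping[str, str | Path], death_slack_days: int = 0
) -> TableBundle:
    """Load and validate the four input tables from CSV or Parquet.

    ``paths`` maps table names (persons/enrollment/claims/cancer) to files;
    format is inferred from the suffix.
    """
    frames = {}
    for name in _TABLE_SCHEMAS:
        if name not in paths:
            raise SchemaError(f"no path given for table {name!r}")
        p = Path(paths[name])
        if p.suffix == ".parquet":
            df = pd.read_parquet(p)
        else:
            df = pd.read_csv(p, dtype="object")
        frames[name] = _coerce_table(df, name)
    bundle = TableBundle(
        frames["persons"], frames["enrollment"], frames["claims"], frames["cancer"]
    )
    return validate_bundle(bundle, death_slack_days=death_slack_days)


def write_tables(bundle: TableBundle, out_dir: str | Path, fmt: str = "csv") -> dict:
    """Write the bundle; returns the path map accepted by :func:`read_tables`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in _TABLE_SCHEMAS:
        df = getattr(bundle, name)
        path = out / f"{name}.{'parquet' if fmt == 'parquet' else 'csv'}"
        if fmt == "parquet":
            df.to_parquet(path, index=False)
        else:
            df2 = df.copy()
            for col, kind in _TABLE_SCHEMAS[name].items():
                if kind == "date":
                    df2[col] = df2[col].dt.strftime("%Y-%m-%d")
            df2.to_csv(path, index=False)
        paths[name] = path
    return paths


def in_window(service_date, anchor, lookback_days: int = DEFAULT_LOOKBACK_DAYS):
    """Half-open ascertainment window: ``anchor - L <= d < anchor``.

    Accepts scalars or aligned array-likes of datetime64; the anchor day
    itself is excluded by convention.
    """
    if lookback_days <= 0:
        raise ValueError("lookback_days must be positive")
    d = pd.to_datetime(service_date)
    a = pd.to_datetime(anchor)
    lo = a - pd.to_timedelta(lookback_days, unit="D")
    return (d >= lo) & (d < a)


def continuous_enrollment(
    spells: pd.DataFrame,
    start,
    end,
    coverage: str = "FFS",
    gap_tolerance_days: int = 0,
) -> bool:
    """True iff the union of ``coverage`` spells covers [start, end].

    Adjacent spells may abut (end of one = start of the next counts as no
    gap); ``gap_tolerance_days`` allows administrative 1-day artifacts.
    """
    start = pd.Timestamp(start)
    end = pd.Timestamp(end)
    if start > end:
        raise ValueError("start after end")
    sub = spells[spells["coverage"] == coverage]
    sub = sub[(sub["end_date"] >= start) & (sub["start_date"] <= end)]
    if sub.empty:
        return False
    sub = sub.sort_values("start_date")
    # covered_until = last covered day so far; a spell may start at most
    # gap_tolerance + 1 days after it without opening a gap
    covered_until = start - pd.Timedelta(days=1)
    max_step = pd.Timedelta(days=gap_tolerance_days + 1)
    for s, e in zip(sub["start_date"], sub["end_date"]):
        if s - covered_until > max_step:
            return False
        covered_until = max(covered_until, e)
        if covered_until >= end:
            return True
    return covered_until >= end


def month_anchor(index_date, month: int):
    """Anchor date of follow-up month ``m`` under the 30-day convention."""
    return pd.Timestamp(index_date) + pd.Timedelta(days=DAYS_PER_MONTH * month)


def anchors_for(index_date, months: Iterable[int]) -> list[pd.Timestamp]:
    return [month_anchor(index_date, m) for m in months]
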