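"""Claims-based frailty scoring.

The frailty proxy is a logistic-model score: binary indicator flags are
extracted from claims in a 180-day lookback window before an anchor date,
combined with demographics in a linear predictor, and mapped through the
inverse logit to a predicted probability of frailty in (0, 1).  Higher
scores mean a higher probability of being frail.

The fitted coefficients of the published index are not reproduced here; the
package ships a documented synthetic default set (deficit indicators
positive, screening indicators negative) calibrated so that cohort-level
mean scores on the synthetic generator fall in the realistic 0.03-0.07
range.  Users can override every coefficient via YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .claims_core import (
    DAYS_PER_MONTH,
    DEFAULT_LOOKBACK_DAYS,
    FRAILTY_INDICATORS,
    SCREENING_INDICATORS,
    CodeMap,
    in_window,
)

# Synthetic default indicator coefficients.  Signs follow the deficit /
# screening split; magnitudes are plausible log-odds contributions chosen
# during generator calibration (see docs/methods.md), not published values.
DEFAULT_INDICATOR_COEFFICIENTS = {
    "parkinson_disease": 0.90,
    "home_hospital_bed": 1.00,
    "wheelchair": 0.90,
    "home_oxygen": 0.80,
    "paralysis": 0.90,
    "podiatric_care": 0.35,
    "psychiatric_diagnoses": 0.50,
    "dementia": 0.80,
    "skin_ulcer_decubitus": 0.80,
    "stroke_brain_injury": 0.70,
    "ambulance_life_support": 0.70,
    "bladder_dysfunction": 0.50,
    "arthritis_joint_conditions": 0.30,
    "vertigo": 0.30,
    "heart_failure": 0.50,
    "weakness": 0.60,
    "lipid_abnormality": -0.50,
    "rehabilitation_services": 0.30,
    "cancer_screening": -0.60,
    "hypotension_shock": 0.60,
}

DEFAULT_RACE_TERMS = {
    "White": 0.0,
    "Black": 0.10,
    "Hispanic": 0.05,
    "API": 0.0,
    "AI/AN": 0.05,
    "missing": 0.0,
}


@dataclass(frozen=True)
class FrailtyModel:
    """Logistic frailty-score model: intercept + demographics + indicators."""

    intercept: float = -3.41
    age_coefficient: float = 0.025  # per year above 65
    race_terms: dict = field(default_factory=lambda: dict(DEFAULT_RACE_TERMS))
    indicator_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_INDICATOR_COEFFICIENTS)
    )
    removable_screening_set: tuple = tuple(SCREENING_INDICATORS)
    reference_race: str = "White"
    model_id: str = "synthetic-default"

    def __post_init__(self):
        missing = [i for i in FRAILTY_INDICATORS if i not in self.indicator_coefficients]
        if missing:
            raise ValueError(f"model lacks coefficients for indicators: {missing}")

    @classmethod
    def from_yaml(cls, path) -> "FrailtyModel":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            intercept=float(raw["intercept"]),
            age_coefficient=float(raw.get("age_coefficient", 0.0)),
            race_terms=dict(raw.get("race_terms", {})),
            indicator_coefficients={
                k: float(v) for k, v in raw["indicator_coefficients"].items()
            },
            removable_screening_set=tuple(
                raw.get("removable_screening_set", SCREENING_INDICATORS)
            ),
            model_id=str(raw.get("model_id", "user-yaml")),
        )


@dataclass
class IndicatorVector:
    """Binary indicator flags plus demographics at a single anchor date."""

    person_id: str
    anchor: pd.Timestamp
    flags: dict
    age_at_anchor: float
    race_ethnicity: str


@dataclass
class FrailtyScore:
    person_id: str
    anchor: pd.Timestamp
    score: float
    model_id: str


def age_at(anchor, birth_year: int) -> int:
    """Age in whole years at the anchor; birth months are not recorded, so
    age is simply anchor year minus birth year."""
    return pd.Timestamp(anchor).year - int(birth_year)


def extract_indicators(
    claims: pd.DataFrame,
    person: pd.Series,
    anchor,
    lookback_days: int = DEFAULT_LOOKBACK_DAYS,
    codemap: CodeMap | None = None,
) -> IndicatorVector:
    """Flags for one person at one anchor (any mapped claim in window)."""
    codemap = codemap or CodeMap.synthetic_identity()
    anchor = pd.Timestamp(anchor)
    sub = claims[claims["person_id"] == person["person_id"]]
    flags = {ind: 0 for ind in FRAILTY_INDICATORS}
    if len(sub):
        ind = codemap.translate(sub)
        ok = in_window(sub["service_date"], anchor, lookback_days)
        for name in ind[np.asarray(ok) & ind.notna().to_numpy()]:
            if name in flags:
                flags[name] = 1
    return IndicatorVector(
        person_id=person["person_id"],
        anchor=anchor,
        flags=flags,
        age_at_anchor=age_at(anchor, person["birth_year"]),
        race_ethnicity=str(person["race_ethnicity"]),
    )


def linear_predictor(model: FrailtyModel, iv: IndicatorVector) -> float:
    race = iv.race_ethnicity
    if race not in model.race_terms:
        race = model.reference_race
    eta = (
        model.intercept
        + model.age_coefficient * (iv.age_at_anchor - 65.0)
        + model.race_terms.get(race, 0.0)
    )
    for name, coef in model.indicator_coefficients.items():
        eta += coef * iv.flags.get(name, 0)
    return float(eta)


def score(model: FrailtyModel, iv: IndicatorVector) -> FrailtyScore:
    """Frailty score = inverse-logit of the linear predictor; always (0,1)."""
    return FrailtyScore(
        person_id=iv.person_id,
        anchor=iv.anchor,
        score=float(expit(linear_predictor(model, iv))),
        model_id=model.model_id,
    )


def apply_sensitivity(model: FrailtyModel, removed) -> FrailtyModel:
    """Return a model with the given indicators' coefficients forced to 0.

    Flags are still extracted (for prevalence reporting); only the score
    contribution is removed.  Idempotent.
    """
    removed = list(removed)
    unknown = [r for r in removed if r not in FRAILTY_INDICATORS]
    if unknown:
        raise ValueError(f"unknown indicators: {unknown}")
    if not removed:
        return model
    coefs = dict(model.indicator_coefficients)
    for r in removed:
        coefs[r] = 0.0
    suffix = "-minus-" + "+".join(sorted(removed))
    mid = model.model_id
    if not mid.endswith(suffix):
        mid = mid + suffix
    return replace(model, indicator_coefficients=coefs, model_id=mid)


# ---------------------------------------------------------------------------
# Vectorized scoring over many (row, anchor) pairs
# ---------------------------------------------------------------------------

def indicator_matrix(
    claims: pd.DataFrame,
    anchor_frame: pd.DataFrame,
    lookback_days: int = DEFAULT_LOOKBACK_DAYS,
    codemap: CodeMap | None = None,
) -> pd.DataFrame:
    """Binary indicator flags for every row of ``anchor_frame``.

    ``anchor_frame`` needs columns ``row_id`` (unique), ``person_id`` and
    ``anchor``.  Returns a row_id-indexed frame with one 0/1 column per
    frailty indicator.  Unmapped claim codes are ignored (counted in
    ``result.attrs['n_unmapped']``).
    """
    codemap = codemap or CodeMap.synthetic_identity()
    out = pd.DataFrame(
        0, index=pd.Index(anchor_frame["row_id"], name="row_id"),
        columns=FRAILTY_INDICATORS, dtype="int8",
    )
    if not len(claims):
        out.attrs["n_unmapped"] = 0
        return out
    cl = claims[["person_id", "service_date", "code", "code_system"]].copy()
    cl["indicator"] = codemap.translate(cl)
    n_unmapped = int(cl["indicator"].isna().sum())
    cl = cl.dropna(subset=["indicator"])
    cl = cl[cl["indicator"].isin(FRAILTY_INDICATORS)]
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
    out.attrs["n_unmapped"] = n_unmapped
    return out


def score_matrix(
    model: FrailtyModel,
    indicators: pd.DataFrame,
    demographics: pd.DataFrame,
) -> pd.Series:
    """Vectorized scores; ``demographics`` is row_id-indexed with columns
    ``age_at_anchor`` and ``race_ethnicity`` aligned to ``indicators``."""
    coefs = np.array([model.indicator_coefficients[i] for i in FRAILTY_INDICATORS])
    eta = indicators[FRAILTY_INDICATORS].to_numpy() @ coefs
    race = demographics["race_ethnicity"].map(model.race_terms)
    race = race.fillna(model.race_terms.get(model.reference_race, 0.0))
    eta = (
        eta
        + model.intercept
        + model.age_coefficient * (demographics["age_at_anchor"].to_numpy() - 65.0)
        + race.to_numpy()
    )
    return pd.Series(expit(eta), index=indicators.index, name="score")


def observation_end(
    persons: pd.DataFrame, enrollment: pd.DataFrame, pairs: pd.DataFrame
) -> pd.DataFrame:
    """Last observed date for each (person_id, index_date) pair.

    Observation ends at death or at the end of the merged FFS enrollment
    spell containing the index date (disenrollment), whichever is first.
    Returns ``pairs`` with an added ``observation_end`` column (NaT when the
    person is not FFS-enrolled on the index date).
    """
    ffs = enrollment[enrollment["coverage"] == "FFS"].sort_values(
        ["person_id", "start_date"]
    )
    grouped = {pid: g for pid, g in ffs.groupby("person_id")}
    death = persons.set_index("person_id")["death_date"]
    ends = []
    for pid, idx_date in zip(pairs["person_id"], pairs["index_date"]):
        g = grouped.get(pid)
        end = pd.NaT
        if g is not None:
            covered_until = None
            for s, e in zip(g["start_date"], g["end_date"]):
                if covered_until is None:
                    if s <= idx_date <= e:
                        covered_until = e
                elif s <= covered_until + pd.Timedelta(days=1):
                    covered_until = max(covered_until, e)
                else:
                    break
            if covered_until is not None:
                end = covered_until
        d = death.get(pid, pd.NaT)
        if pd.notna(d):
            # death day itself is not an observed anchor
            d = d - pd.Timedelta(days=1)
            end = d if pd.isna(end) else min(end, d)
        ends.append(end)
    out = pairs.copy()
    out["observation_end"] = ends
    return out


def score_series_frame(
    claims: pd.DataFrame,
    persons: pd.DataFrame,
    cohort: pd.DataFrame,
    enrollment: pd.DataFrame,
    model: FrailtyModel | None = None,
    interval_days: int = DAYS_PER_MONTH,
    horizon_days: int = 360,
    lookback_days: int = DEFAULT_LOOKBACK_DAYS,
    codemap: CodeMap | None = None,
) -> pd.DataFrame:
    """Monthly frailty-score series for every cohort row.

    ``cohort`` needs ``person_id`` and ``index_date`` (and may carry a
    ``row_id``; one is created otherwise — comparator persons matched to
    several cases appear once per match with their own index date).  Anchors
    run from day 0 to ``horizon_days`` in steps of ``interval_days``; anchors
    after death or FFS disenrollment are omitted, so missingness is always a
    suffix of the series.
    """
    model = model or FrailtyModel()
    cohort = cohort.copy()
    if "row_id" not in cohort.columns:
        cohort["row_id"] = np.arange(len(cohort))
    months = np.arange(0, horizon_days + 1, interval_days)

    pairs = cohort[["person_id", "index_date"]].drop_duplicates()
    obs_end = observation_end(persons, enrollment, pairs)

    rows = cohort.loc[:, ["row_id", "person_id", "index_date"]]
    long = rows.loc[rows.index.repeat(len(months))].reset_index(drop=True)
    long["offset_days"] = np.tile(months, len(rows))
    long["anchor"] = long["index_date"] + pd.to_timedelta(long["offset_days"], unit="D")
    long = long.merge(obs_end, on=["person_id", "index_date"], how="left")
    long["observed"] = long["anchor"] <= long["observation_end"]
    obs = long[long["observed"]].copy()
    obs["pair_id"] = np.arange(len(obs))

    af = obs.rename(columns={"pair_id": "row_id_pair"})[
        ["row_id_pair", "person_id", "anchor"]
    ].rename(columns={"row_id_pair": "row_id"})
    flags = indicator_matrix(claims, af, lookback_days, codemap)

    pers = persons.set_index("person_id")
    demo = pd.DataFrame(
        {
            "age_at_anchor": obs["anchor"].dt.year.to_numpy()
            - obs["person_id"].map(pers["birth_year"]).to_numpy(),
            "race_ethnicity": obs["person_id"].map(pers["race_ethnicity"]).to_numpy(),
        },
        index=flags.index,
    )
    obs["score"] = score_matrix(model, flags, demo).to_numpy()
    result = obs[["row_id", "person_id", "index_date", "offset_days", "anchor", "score"]]
    result = result.assign(month=result["offset_days"] // interval_days)
    result.attrs["model_id"] = model.model_id
    return result.reset_index(drop=True)


def score_series(
    claims: pd.DataFrame,
    person: pd.Series,
    t0,
    enrollment: pd.DataFrame,
    model: FrailtyModel | None = None,
    interval_days: int = DAYS_PER_MONTH,
    horizon_days: int = 360,
    lookback_days: int = DEFAULT_LOOKBACK_DAYS,
    codemap: CodeMap | None = None,
) -> list[FrailtyScore]:
    """Monthly score sequence for a single person (wrapper over the
    vectorized path)."""
    model = model or FrailtyModel()
    persons = pd.DataFrame([person])
    cohort = pd.DataFrame(
        {"person_id": [person["person_id"]], "index_date": [pd.Timestamp(t0)]}
    )
    frame = score_series_frame(
        claims, persons, cohort, enrollment, model,
        interval_days, horizon_days, lookback_days, codemap,
    )
    return [
        FrailtyScore(r.person_id, r.anchor, r.score, model.model_id)
        for r in frame.itertuples()
    ]


def indicator_prevalence(
    cohort: pd.DataFrame,
    anchors: dict,
    claims: pd.DataFrame,
    persons: pd.DataFrame,
    enrollment: pd.DataFrame,
    lookback_days: int = DEFAULT_LOOKBACK_DAYS,
    codemap: CodeMap | None = None,
) -> pd.DataFrame:
    """Fraction of persons with each indicator flag set, per named anchor.

    ``anchors`` maps a label (e.g. ``"T2"``) to a day offset from each row's
    index date.  Only persons still under observation at the anchor count in
    the denominator.
    """
    if not len(cohort):
        raise ValueError("empty cohort")
    cohort = cohort.copy()
    if "row_id" not in cohort.columns:
        cohort["row_id"] = np.arange(len(cohort))
    pairs = cohort[["person_id", "index_date"]].drop_duplicates()
    obs_end = observation_end(persons, enrollment, pairs)
    out = {}
    for label, offset in anchors.items():
        af = cohort[["row_id", "person_id", "index_date"]].copy()
        af["anchor"] = af["index_date"] + pd.Timedelta(days=int(offset))
        af = af.merge(obs_end, on=["person_id", "index_date"], how="left")
        af = af[af["anchor"] <= af["observation_end"]]
        flags = indicator_matrix(claims, af, lookback_days, codemap)
        out[label] = flags.mean(axis=0)
    return pd.DataFrame(out)
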