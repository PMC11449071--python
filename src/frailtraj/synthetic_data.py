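"""Synthetic Medicare-like claims generator.

Every downstream stage of the pipeline is exercised on data from this
module, because the real linked registry-claims data it emulates are only
available under a data use agreement.  The generator reproduces the
*latent structure* the analysis assumes:

* a chemotherapy cohort whose members belong to one of six latent frailty
  trajectory classes (one robust, two resilient, three nonresilient) mixed
  at configurable proportions, plus a matchable noncancer pool with a mild
  age-related upward drift in latent frailty;
* claim-generating processes in which deficit indicators are positively
  loaded on latent frailty and screening services negatively loaded
  (logistic link from latent frailty to the per-180-day-window claim
  probability), with a treatment-period suppression of screening claims in
  the chemotherapy arm emulating deferral of routine care;
* frailty-dependent death and disenrollment hazards per 30-day block
  (informative attrition).

Ground truth (class labels, latent series, attrition times) is emitted
separately and is never read by any analysis stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy import stats

from .claims_core import (
    DAYS_PER_MONTH,
    FRAILTY_INDICATORS,
    GAGNE_CONDITIONS,
    TIMEPOINT_OFFSETS,
    TableBundle,
    validate_bundle,
)

N_CLASSES = 6
N_ANCHORS = 13  # months 0..12

CLASS_NAMES = [
    "robust",
    "resilient_low_med",
    "resilient_med_high",
    "nonresilient_low_med",
    "nonresilient_low_high",
    "nonresilient_high",
]

# Latent monthly severity, months 0..12 from chemotherapy initiation, on an
# abstract 0-1 scale that the claim loadings map to frailty scores.  Shapes:
# flat (robust), a sharp treatment-period rise that resolves (resilient),
# monotone worsening (nonresilient).  Levels were calibrated once against
# the default loadings/score model so that the mixture-weighted mean
# *score* rises from ~0.037 at initiation to ~0.055 near the end of
# treatment and partially recovers (~0.049) by month 10.
DEFAULT_LATENT_CURVES = {
    "robust": [0.032] * 13,
    "resilient_low_med": [
        0.035, 0.22, 0.30, 0.20, 0.10, 0.05, 0.042,
        0.040, 0.040, 0.040, 0.040, 0.040, 0.040,
    ],
    "resilient_med_high": [
        0.18, 0.28, 0.35, 0.30, 0.24, 0.21, 0.20,
        0.20, 0.19, 0.19, 0.19, 0.19, 0.19,
    ],
    "nonresilient_low_med": [
        0.035, 0.053, 0.071, 0.089, 0.107, 0.125, 0.143,
        0.161, 0.179, 0.197, 0.215, 0.232, 0.25,
    ],
    "nonresilient_low_high": [
        0.05, 0.0875, 0.125, 0.1625, 0.20, 0.2375, 0.275,
        0.3125, 0.35, 0.3875, 0.425, 0.4625, 0.50,
    ],
    "nonresilient_high": [
        0.22, 0.2467, 0.2733, 0.30, 0.3133, 0.3267, 0.34,
        0.3533, 0.3667, 0.38, 0.3867, 0.3933, 0.40,
    ],
}

#: Default cluster mixture: robust 78%, resilient 15% + 1%,
#: nonresilient 4% + 1% + 1%.
DEFAULT_CLUSTER_MIXTURE = (0.78, 0.15, 0.01, 0.04, 0.01, 0.01)

# (a_j, b_j): P(any claim for indicator j in a 180-day window) =
# expit(a_j + b_j * latent).  Negative b marks screening services.
# Intercepts anchor realistic window prevalences near latent ~0.04;
# slopes were steepened during the one-off calibration so that cohort mean
# scores span the intended 0.037-0.06 range.
DEFAULT_INDICATOR_LOADINGS = {
    "parkinson_disease": (-4.76, 8.0),
    "home_hospital_bed": (-5.44, 12.0),
    "wheelchair": (-4.84, 12.0),
    "home_oxygen": (-4.40, 10.0),
    "paralysis": (-5.40, 10.0),
    "podiatric_care": (-2.38, 4.0),
    "psychiatric_diagnoses": (-1.57, 6.0),
    "dementia": (-4.18, 9.0),
    "skin_ulcer_decubitus": (-4.62, 11.0),
    "stroke_brain_injury": (-4.36, 8.0),
    "ambulance_life_support": (-3.88, 14.0),
    "bladder_dysfunction": (-3.56, 8.0),
    "arthritis_joint_conditions": (-1.28, 4.0),
    "vertigo": (-3.10, 5.0),
    "heart_failure": (-2.04, 7.0),
    "weakness": (-3.20, 10.0),
    "lipid_abnormality": (0.77, -6.0),
    "rehabilitation_services": (-2.96, 8.0),
    "cancer_screening": (0.69, -12.0),
    "hypotension_shock": (-4.20, 10.0),
}

DEFAULT_GAGNE_LOADINGS = {
    "congestive_heart_failure": (-2.34, 7.0),
    "dementia_comorbid": (-3.66, 8.0),
    "renal_failure": (-3.32, 6.0),
    "weight_loss": (-4.00, 10.0),
    "cardiac_arrhythmia": (-2.08, 4.0),
    "chronic_pulmonary_disease": (-2.28, 4.0),
    "complicated_diabetes": (-2.28, 4.0),
    "deficiency_anemia": (-2.10, 5.0),
    "liver_disease": (-3.88, 4.0),
    "peripheral_vascular_disease": (-2.70, 5.0),
    "psychosis": (-4.12, 6.0),
    "fluid_electrolyte_disorders": (-2.64, 7.0),
    "hemiplegia": (-4.66, 8.0),
    "hypertension_uncomplicated": (0.16, 2.0),
}

CHEMO_RACE_PROBS = {
    "White": 0.816, "Black": 0.089, "Hispanic": 0.055, "API": 0.037, "AI/AN": 0.003,
}
POOL_RACE_PROBS = {
    "White": 0.759, "Black": 0.093, "Hispanic": 0.083, "API": 0.061, "AI/AN": 0.004,
}
REGION_PROBS = {"Northeast": 0.194, "West": 0.416, "Midwest": 0.191, "South": 0.199}
STAGE_PROBS = {"I": 0.223, "II": 0.537, "III": 0.240}
GRADE_PROBS = {
    "well": 0.086, "moderate": 0.391, "poor": 0.516, "undifferentiated": 0.007,
}
SURGERY_PROBS = {"mastectomy": 0.401, "BCT": 0.599}

POOL_ORIGIN = pd.Timestamp("2003-01-01")
POOL_MONTHS = 202  # 30-day blocks through mid-2019
POOL_END = pd.Timestamp("2019-12-31")


@dataclass(frozen=True)
class HazardConfig:
    """Per-30-day-block logistic hazard on latent frailty."""

    intercept: float
    latent_coefficient: float
    chemo_offset: float = 0.0

    def monthly_probability(self, latent, chemo: bool = False):
        eta = self.intercept + self.latent_coefficient * np.asarray(latent)
        if chemo:
            eta = eta + self.chemo_offset
        return expit(eta)


@dataclass(frozen=True)
class AttritionConfig:
    death: HazardConfig = HazardConfig(-7.35, 6.0, chemo_offset=1.0)
    disenrollment: HazardConfig = HazardConfig(-7.30, 4.0, chemo_offset=0.0)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic cohort.

    Defaults encode the emulated study: mixture (0.78, 0.15, 0.01, 0.04,
    0.01, 0.01) over robust / resilient / nonresilient classes, a
    chemotherapy-arm latent trajectory whose mixture mean rises from
    ~0.037 and partially recovers, a comparator pool drifting mildly
    upward (~0.055 to ~0.062 over 12 months), and attrition hazards giving
    roughly 3% chemo-arm and 1% comparator deaths within 10 months.
    """

    n_chemo: int = 2000
    comparator_pool_multiplier: float = 5.0
    cluster_mixture: tuple = DEFAULT_CLUSTER_MIXTURE
    latent_curves: dict = field(default_factory=lambda: {
        k: list(v) for k, v in DEFAULT_LATENT_CURVES.items()
    })
    #: mean latent severity at month 0 and month 12 (latent units; under the
    #: default loadings the gamma-distributed pool maps to mean scores of
    #: ~0.055 and ~0.062)
    comparator_drift: tuple = (0.058, 0.073)
    indicator_loadings: dict = field(
        default_factory=lambda: dict(DEFAULT_INDICATOR_LOADINGS)
    )
    gagne_loadings: dict = field(default_factory=lambda: dict(DEFAULT_GAGNE_LOADINGS))
    attrition: AttritionConfig = AttritionConfig()
    #: multiplier on screening-service window probabilities in the chemo arm
    #: during treatment months (deferral of routine care), per indicator:
    #: {indicator: (factor months 0-3, factor months 4-6)}
    screening_suppression: dict = field(default_factory=lambda: {
        "cancer_screening": (0.35, 0.65),
        "lipid_abnormality": (0.75, 0.90),
    })
    person_effect_sd: float = 0.012
    contamination_fraction: float = 0.0
    flu_annual_prob_chemo: float = 0.60
    flu_annual_prob_pool: float = 0.48
    mammogram_prob_chemo: float = 0.85
    mammogram_annual_prob_pool: float = 0.40
    seed: int = 42

    def validate(self) -> None:
        if abs(sum(self.cluster_mixture) - 1.0) > 1e-8:
            raise ValueError("cluster_mixture must sum to 1")
        if len(self.cluster_mixture) != N_CLASSES:
            raise ValueError(f"cluster_mixture must have {N_CLASSES} entries")
        for name, curve in self.latent_curves.items():
            arr = np.asarray(curve, dtype=float)
            if arr.shape != (N_ANCHORS,):
                raise ValueError(f"latent curve {name!r} must have {N_ANCHORS} points")
            if (arr < 0).any() or (arr > 1).any():
                raise ValueError(f"latent curve {name!r} outside [0, 1]")


def _choice(rng, probs: dict, n: int) -> np.ndarray:
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    return rng.choice(keys, size=n, p=p)


def _window_to_month_prob(p_window: np.ndarray) -> np.ndarray:
    """Per-30-day-block claim probability consistent with a 180-day-window
    probability under independent monthly draws."""
    return 1.0 - (1.0 - np.clip(p_window, 0.0, 0.999999)) ** (1.0 / 6.0)


def _emit_claims(rng, person_ids, month_dates, p_month, code: str) -> pd.DataFrame:
    """Bernoulli claims: ``p_month`` is (n_persons, n_months); claim day is
    uniform within the 30-day block starting at month_dates[m]."""
    draws = rng.random(p_month.shape) < p_month
    pi, mi = np.nonzero(draws)
    if len(pi) == 0:
        return pd.DataFrame(
            columns=["person_id", "service_date", "code", "code_system"]
        )
    offsets = rng.integers(0, DAYS_PER_MONTH, size=len(pi))
    dates = month_dates[mi] + pd.to_timedelta(offsets, unit="D")
    return pd.DataFrame(
        {
            "person_id": np.asarray(person_ids)[pi],
            "service_date": dates,
            "code": code,
            "code_system": "SYN",
        }
    )


def _first_event_month(rng, p: np.ndarray) -> np.ndarray:
    """First month index with a Bernoulli success per row; -1 if none."""
    draws = rng.random(p.shape) < p
    any_evt = draws.any(axis=1)
    first = np.where(any_evt, draws.argmax(axis=1), -1)
    return first


def generate_population(config: SimConfig) -> tuple[TableBundle, pd.DataFrame]:
    """Generate the full synthetic table bundle plus latent ground truth.

    Returns ``(bundle, truth)`` where ``truth`` holds one row per person
    with arm, latent class (1-6 for the chemo arm, 0 for the pool), the
    monthly latent series (chemo arm), and attrition dates.  Deterministic
    for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_chemo
    n_pool = int(round(config.n_chemo * config.comparator_pool_multiplier))

    # ---------------- chemo arm -------------------------------------------
    chemo_ids = np.array([f"C{i:06d}" for i in range(n)])
    dx_offset = rng.integers(0, (pd.Timestamp("2017-12-31") - pd.Timestamp("2004-01-01")).days + 1, n)
    diagnosis = pd.Timestamp("2004-01-01") + pd.to_timedelta(dx_offset, unit="D")
    age_dx = 65 + np.minimum(np.floor(rng.gamma(2.0, 2.8, n)), 30).astype(int)
    birth_year = diagnosis.year - age_dx
    race = _choice(rng, CHEMO_RACE_PROBS, n)
    region = _choice(rng, REGION_PROBS, n)
    stage = _choice(rng, STAGE_PROBS, n)
    grade = _choice(rng, GRADE_PROBS, n)
    surgery_type = _choice(rng, SURGERY_PROBS, n)
    surgery = diagnosis + pd.to_timedelta(rng.integers(14, 81, n), unit="D")
    chemo_start = surgery + pd.to_timedelta(rng.integers(21, 76, n), unit="D")
    neoadjuvant = np.zeros(n, dtype=bool)

    # eligibility contamination (for exclusion-ledger testing)
    n_bad = int(round(config.contamination_fraction * n))
    if n_bad:
        bad = rng.choice(n, size=n_bad, replace=False)
        kind = rng.integers(0, 3, size=n_bad)
        late_surg = bad[kind == 0]
        surgery = pd.Series(surgery)
        chemo_start = pd.Series(chemo_start)
        surgery.iloc[late_surg] = diagnosis[late_surg] + pd.to_timedelta(
            rng.integers(100, 160, len(late_surg)), unit="D"
        )
        # keep the surgery <= chemo ordering invariant for late surgeries
        chemo_start.iloc[late_surg] = surgery.iloc[late_surg] + pd.to_timedelta(
            rng.integers(21, 76, len(late_surg)), unit="D"
        )
        late_chemo = bad[kind == 1]
        chemo_start.iloc[late_chemo] = surgery.iloc[late_chemo] + pd.to_timedelta(
            rng.integers(100, 160, len(late_chemo)), unit="D"
        )
        neoadjuvant[bad[kind == 2]] = True
        surgery = pd.DatetimeIndex(surgery)
        chemo_start = pd.DatetimeIndex(chemo_start)
    index_date = chemo_start

    # latent trajectories: class curve + person effect, months -18..12
    curves = np.array(
        [config.latent_curves[name] for name in CLASS_NAMES], dtype=float
    )
    classes = rng.choice(N_CLASSES, size=n, p=np.asarray(config.cluster_mixture))
    u = rng.normal(0.0, config.person_effect_sd, n)
    months_rel = np.arange(-18, 13)
    latent = np.empty((n, len(months_rel)))
    for j, m in enumerate(months_rel):
        base = curves[classes, 0] if m < 0 else curves[classes, m]
        latent[:, j] = np.clip(base + u, 0.004, 0.95)

    # attrition (chemo arm: post-index only; cases are alive and enrolled
    # through the index date by construction)
    post = latent[:, months_rel >= 0]  # months 0..12
    p_death = config.attrition.death.monthly_probability(post, chemo=True)
    death_month = _first_event_month(rng, p_death)
    p_dis = config.attrition.disenrollment.monthly_probability(post, chemo=True)
    dis_month = _first_event_month(rng, p_dis)

    death_date = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
    has_death = death_month >= 0
    death_date[has_death] = index_date[has_death] + pd.to_timedelta(
        death_month[has_death] * DAYS_PER_MONTH
        + rng.integers(0, DAYS_PER_MONTH, int(has_death.sum())),
        unit="D",
    )
    dis_date = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
    has_dis = dis_month >= 0
    dis_date[has_dis] = index_date[has_dis] + pd.to_timedelta(
        dis_month[has_dis] * DAYS_PER_MONTH
        + rng.integers(0, DAYS_PER_MONTH, int(has_dis.sum())),
        unit="D",
    )

    enroll_start = diagnosis - pd.Timedelta(days=450)
    enroll_end = pd.Series(index_date + pd.Timedelta(days=420))
    enroll_end = enroll_end.where(dis_date.isna() | (dis_date > enroll_end), dis_date)
    enroll_end = enroll_end.where(death_date.isna() | (death_date > enroll_end), death_date)

    # claims: frailty indicators + comorbidity conditions, months -18..12
    claims_parts: list[pd.DataFrame] = []
    supp03 = {k: v[0] for k, v in config.screening_suppression.items()}
    supp46 = {k: v[1] for k, v in config.screening_suppression.items()}
    for name in FRAILTY_INDICATORS:
        a, b = config.indicator_loadings[name]
        p_window = expit(a + b * latent)
        if name in supp03:
            in_03 = (months_rel >= 0) & (months_rel <= 3)
            in_46 = (months_rel >= 4) & (months_rel <= 6)
            p_window[:, in_03] *= supp03[name]
            p_window[:, in_46] *= supp46[name]
        p_month = _window_to_month_prob(p_window)
        draws = rng.random(p_month.shape) < p_month
        pi, mi = np.nonzero(draws)
        if len(pi):
            offs = rng.integers(0, DAYS_PER_MONTH, len(pi))
            dates = (
                index_date[pi]
                + pd.to_timedelta(months_rel[mi] * DAYS_PER_MONTH + offs, unit="D")
            )
            claims_parts.append(pd.DataFrame({
                "person_id": chemo_ids[pi],
                "service_date": dates,
                "code": name,
                "code_system": "SYN",
            }))
    for name, (a, b) in config.gagne_loadings.items():
        p_month = _window_to_month_prob(expit(a + b * latent))
        draws = rng.random(p_month.shape) < p_month
        pi, mi = np.nonzero(draws)
        if len(pi):
            offs = rng.integers(0, DAYS_PER_MONTH, len(pi))
            dates = (
                index_date[pi]
                + pd.to_timedelta(months_rel[mi] * DAYS_PER_MONTH + offs, unit="D")
            )
            claims_parts.append(pd.DataFrame({
                "person_id": chemo_ids[pi],
                "service_date": dates,
                "code": name,
                "code_system": "SYN",
            }))
    # cancer comorbidity-condition claims after diagnosis (always excluded
    # from the comorbidity score; present to exercise the exclusion rule)
    p_cancer_claim = np.where(months_rel >= 0, 0.25, 0.0)[None, :].repeat(n, 0)
    draws = rng.random(p_cancer_claim.shape) < p_cancer_claim
    pi, mi = np.nonzero(draws)
    if len(pi):
        offs = rng.integers(0, DAYS_PER_MONTH, len(pi))
        claims_parts.append(pd.DataFrame({
            "person_id": chemo_ids[pi],
            "service_date": index_date[pi]
            + pd.to_timedelta(months_rel[mi] * DAYS_PER_MONTH + offs, unit="D"),
            "code": "cancer_nonmetastatic",
            "code_system": "SYN",
        }))

    # service claims: surgery, chemotherapy cycles, mammogram, flu vaccine
    claims_parts.append(pd.DataFrame({
        "person_id": chemo_ids, "service_date": surgery,
        "code": "surgery", "code_system": "SYN",
    }))
    for cycle in range(6):
        claims_parts.append(pd.DataFrame({
            "person_id": chemo_ids,
            "service_date": chemo_start + pd.Timedelta(days=21 * cycle),
            "code": "chemotherapy", "code_system": "SYN",
        }))
    has_mammo = rng.random(n) < config.mammogram_prob_chemo
    claims_parts.append(pd.DataFrame({
        "person_id": chemo_ids[has_mammo],
        "service_date": diagnosis[has_mammo]
        - pd.to_timedelta(rng.integers(30, 331, int(has_mammo.sum())), unit="D"),
        "code": "mammogram", "code_system": "SYN",
    }))
    for year_block in (-2, -1, 0):
        has_flu = rng.random(n) < config.flu_annual_prob_chemo
        claims_parts.append(pd.DataFrame({
            "person_id": chemo_ids[has_flu],
            "service_date": index_date[has_flu]
            + pd.to_timedelta(
                360 * year_block + rng.integers(0, 360, int(has_flu.sum())), unit="D"
            ),
            "code": "flu_vaccine", "code_system": "SYN",
        }))

    chemo_claims = pd.concat(claims_parts, ignore_index=True)
    # truncate at death / disenrollment / enrollment end
    cd = chemo_claims["person_id"].map(pd.Series(death_date.values, index=chemo_ids))
    ce = chemo_claims["person_id"].map(pd.Series(enroll_end.values, index=chemo_ids))
    keep = (cd.isna() | (chemo_claims["service_date"] <= cd)) & (
        chemo_claims["service_date"] <= ce
    )
    cs = chemo_claims["person_id"].map(
        pd.Series(pd.Series(enroll_start).values, index=chemo_ids)
    )
    keep &= chemo_claims["service_date"] >= cs
    chemo_claims = chemo_claims[keep].reset_index(drop=True)

    chemo_persons = pd.DataFrame({
        "person_id": chemo_ids,
        "birth_year": np.asarray(birth_year),
        "sex": "F",
        "race_ethnicity": race,
        "region": region,
        "death_date": death_date.values,
    })
    chemo_enroll = pd.DataFrame({
        "person_id": chemo_ids,
        "start_date": enroll_start,
        "end_date": enroll_end.values,
        "coverage": "FFS",
    })
    cancer = pd.DataFrame({
        "person_id": chemo_ids,
        "diagnosis_date": diagnosis,
        "stage": stage,
        "grade": grade,
        "surgery_date": surgery,
        "surgery_type": surgery_type,
        "chemo_start_date": chemo_start,
        "neoadjuvant_flag": neoadjuvant,
    })

    # ---------------- comparator pool -------------------------------------
    pool_ids = np.array([f"N{i:06d}" for i in range(n_pool)])
    pool_birth_year = rng.choice(np.asarray(birth_year), size=n_pool)
    pool_region = rng.choice(region, size=n_pool)
    pool_race = _choice(rng, POOL_RACE_PROBS, n_pool)

    drift_start, drift_end = config.comparator_drift
    drift_per_year = drift_end - drift_start
    base = np.clip(rng.gamma(2.0, drift_start / 2.0, n_pool), 0.004, 0.8)
    pool_month_dates = POOL_ORIGIN + pd.to_timedelta(
        np.arange(POOL_MONTHS) * DAYS_PER_MONTH, unit="D"
    )
    # latent tied to age so that, at matched ages (~70), the pool mean sits
    # near drift_start and rises by drift_per_year each year of follow-up
    age_at_month = (
        pool_month_dates.year.values[None, :] - pool_birth_year[:, None]
    ).astype(float)
    pool_latent = np.clip(
        base[:, None] + drift_per_year * (age_at_month - 70.0), 0.004, 0.95
    )

    p_death = config.attrition.death.monthly_probability(pool_latent, chemo=False)
    pool_death_month = _first_event_month(rng, p_death)
    p_dis = config.attrition.disenrollment.monthly_probability(pool_latent, chemo=False)
    pool_dis_month = _first_event_month(rng, p_dis)

    pool_death_date = pd.Series(pd.NaT, index=range(n_pool), dtype="datetime64[ns]")
    hd = pool_death_month >= 0
    pool_death_date[hd] = pool_month_dates[pool_death_month[hd]] + pd.to_timedelta(
        rng.integers(0, DAYS_PER_MONTH, int(hd.sum())), unit="D"
    )
    pool_dis_date = pd.Series(pd.NaT, index=range(n_pool), dtype="datetime64[ns]")
    hdd = pool_dis_month >= 0
    pool_dis_date[hdd] = pool_month_dates[pool_dis_month[hdd]] + pd.to_timedelta(
        rng.integers(0, DAYS_PER_MONTH, int(hdd.sum())), unit="D"
    )
    pool_end = pd.Series(POOL_END, index=range(n_pool))
    pool_end = pool_end.where(
        pool_dis_date.isna() | (pool_dis_date > pool_end), pool_dis_date
    )
    pool_end = pool_end.where(
        pool_death_date.isna() | (pool_death_date > pool_end), pool_death_date
    )

    pool_parts: list[pd.DataFrame] = []
    for name in FRAILTY_INDICATORS:
        a, b = config.indicator_loadings[name]
        p_month = _window_to_month_prob(expit(a + b * pool_latent))
        pool_parts.append(
            _emit_claims(rng, pool_ids, pool_month_dates, p_month, name)
        )
    for name, (a, b) in config.gagne_loadings.items():
        p_month = _window_to_month_prob(expit(a + b * pool_latent))
        pool_parts.append(
            _emit_claims(rng, pool_ids, pool_month_dates, p_month, name)
        )
    # flu vaccine and screening mammograms, annual
    years = np.arange(2003, 2019)
    for y in years:
        y0 = pd.Timestamp(f"{y}-01-01")
        has_flu = rng.random(n_pool) < config.flu_annual_prob_pool
        pool_parts.append(pd.DataFrame({
            "person_id": pool_ids[has_flu],
            "service_date": y0
            + pd.to_timedelta(rng.integers(0, 365, int(has_flu.sum())), unit="D"),
            "code": "flu_vaccine", "code_system": "SYN",
        }))
        has_m = rng.random(n_pool) < config.mammogram_annual_prob_pool
        pool_parts.append(pd.DataFrame({
            "person_id": pool_ids[has_m],
            "service_date": y0
            + pd.to_timedelta(rng.integers(0, 365, int(has_m.sum())), unit="D"),
            "code": "mammogram", "code_system": "SYN",
        }))
    pool_claims = pd.concat([p for p in pool_parts if len(p)], ignore_index=True)
    cd = pool_claims["person_id"].map(pd.Series(pool_death_date.values, index=pool_ids))
    ce = pool_claims["person_id"].map(pd.Series(pool_end.values, index=pool_ids))
    keep = (cd.isna() | (pool_claims["service_date"] <= cd)) & (
        pool_claims["service_date"] <= ce
    )
    pool_claims = pool_claims[keep].reset_index(drop=True)

    pool_persons = pd.DataFrame({
        "person_id": pool_ids,
        "birth_year": pool_birth_year,
        "sex": "F",
        "race_ethnicity": pool_race,
        "region": pool_region,
        "death_date": pool_death_date.values,
    })
    pool_enroll = pd.DataFrame({
        "person_id": pool_ids,
        "start_date": POOL_ORIGIN,
        "end_date": pool_end.values,
        "coverage": "FFS",
    })

    persons = pd.concat([chemo_persons, pool_persons], ignore_index=True)
    enrollment = pd.concat([chemo_enroll, pool_enroll], ignore_index=True)
    claims = pd.concat([chemo_claims, pool_claims], ignore_index=True)
    claims = claims.sort_values(
        ["person_id", "service_date", "code"], kind="stable"
    ).reset_index(drop=True)
    persons["death_date"] = pd.to_datetime(persons["death_date"])

    bundle = TableBundle(
        persons=persons.astype({"person_id": "string", "sex": "string",
                                "race_ethnicity": "string", "region": "string"}),
        enrollment=enrollment.astype({"person_id": "string", "coverage": "string"}),
        claims=claims.astype({"person_id": "string", "code": "string",
                              "code_system": "string"}),
        cancer=cancer.astype({"person_id": "string", "stage": "string",
                              "grade": "string", "surgery_type": "string"}),
    )
    validate_bundle(bundle)

    truth_chemo = pd.DataFrame({
        "person_id": chemo_ids,
        "arm": "chemo",
        "true_class": classes + 1,
        "death_date": death_date.values,
        "disenrollment_date": dis_date.values,
    })
    post_cols = latent[:, months_rel >= 0]
    for m in range(N_ANCHORS):
        truth_chemo[f"latent_m{m}"] = post_cols[:, m]
    truth_pool = pd.DataFrame({
        "person_id": pool_ids,
        "arm": "comparator_pool",
        "true_class": 0,
        "death_date": pool_death_date.values,
        "disenrollment_date": pool_dis_date.values,
    })
    for m in range(N_ANCHORS):
        truth_pool[f"latent_m{m}"] = np.nan
    truth = pd.concat([truth_chemo, truth_pool], ignore_index=True)
    return bundle, truth


# ---------------------------------------------------------------------------
# Direct simulators for estimator tests
# ---------------------------------------------------------------------------

def generate_gee_scenario(
    betas,
    dispersion: float,
    ar_rho: float,
    n: int,
    seed: int,
    chemo_fraction: float = 0.5,
) -> pd.DataFrame:
    """Simulate the three-timepoint marginal-model estimand directly.

    Outcomes have gamma marginals with mean ``b0 + b1*arm + b2*t2 + b3*t3 +
    b4*arm*t2 + b5*arm*t3`` and variance ``dispersion * mean^2``; the
    within-person dependence across T1-T3 is a Gaussian copula with AR(1)
    correlation ``ar_rho``.  Returns a long panel (person_id, arm,
    timepoint, score, weight=1, observed=True).
    """
    b = np.asarray(betas, dtype=float)
    if b.shape != (6,):
        raise ValueError("betas must have 6 elements")
    rng = np.random.default_rng(seed)
    arm = (rng.random(n) < chemo_fraction).astype(int)
    t2 = np.array([0, 1, 0])
    t3 = np.array([0, 0, 1])
    mu = (
        b[0]
        + b[1] * arm[:, None]
        + b[2] * t2[None, :]
        + b[3] * t3[None, :]
        + b[4] * (arm[:, None] * t2[None, :])
        + b[5] * (arm[:, None] * t3[None, :])
    )
    if (mu <= 0).any():
        raise ValueError("implied cell means must be positive for gamma outcomes")
    corr = np.array([
        [1.0, ar_rho, ar_rho ** 2],
        [ar_rho, 1.0, ar_rho],
        [ar_rho ** 2, ar_rho, 1.0],
    ])
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, 3)) @ chol.T
    uniforms = stats.norm.cdf(z)
    shape = 1.0 / max(dispersion, 1e-12)
    y = stats.gamma.ppf(uniforms, a=shape, scale=mu * dispersion if dispersion > 0 else 0)
    if dispersion <= 0:
        y = mu.copy()
    panel = pd.DataFrame({
        "person_id": np.repeat([f"P{i:06d}" for i in range(n)], 3),
        "arm": np.repeat(np.where(arm == 1, "chemo", "comparator"), 3),
        "timepoint": np.tile(["T1", "T2", "T3"], n),
        "score": y.ravel(),
        "weight": 1.0,
        "observed": True,
    })
    return panel


def generate_trajectory_mixture(
    n: int,
    mixture=DEFAULT_CLUSTER_MIXTURE,
    class_curves: dict | None = None,
    noise_sd: float = 0.01,
    dropout_fraction: float = 0.0,
    min_observed: int = 3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Score-space trajectory mixture for clustering validation.

    Draws each person's 13-anchor trajectory as a class mean curve plus
    independent Gaussian anchor noise, optionally truncating a fraction of
    persons to a shorter observed prefix (informative: persons with higher
    mean latent frailty are more likely to drop out).  Returns
    ``(trajectories, true_classes)`` with NaN suffixes for dropouts.
    """
    rng = np.random.default_rng(seed)
    curves = DEFAULT_LATENT_CURVES if class_curves is None else class_curves
    names = list(curves)
    mat = np.array([curves[k] for k in names], dtype=float)
    classes = rng.choice(len(names), size=n, p=np.asarray(mixture, dtype=float))
    X = mat[classes] + rng.normal(0.0, noise_sd, size=(n, mat.shape[1]))
    X = np.clip(X, 1e-4, 1.0)
    if dropout_fraction > 0:
        sev = mat[classes].mean(axis=1)
        w = sev / sev.mean()
        p_drop = np.clip(dropout_fraction * w, 0.0, 0.95)
        drops = rng.random(n) < p_drop
        n_obs = rng.integers(min_observed, mat.shape[1], size=n)
        for i in np.nonzero(drops)[0]:
            X[i, n_obs[i]:] = np.nan
    return X, classes + 1
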