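"""Baseline predictors of nonresilient frailty trajectories.

A logistic regression contrasts membership in a nonresilient trajectory
cluster against robust-or-resilient membership, with the covariate layout
of the emulated study: age centered at 65 (per year), race (reference
non-Hispanic White, with the two smallest groups collapsed into "Other"),
region (reference West), stage (reference I), surgery type (reference
breast-conserving), tumor grade (reference well differentiated),
comorbidity category (reference <=0), preindex flu vaccine, and the 20
baseline frailty-indicator flags.  Effects are reported as odds ratios
with Wald 95% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .claims_core import FRAILTY_INDICATORS
from .weighting import SeparationError

RACE_COLLAPSE = {"API": "Other", "AI/AN": "Other"}
RACE_LEVELS = ["Black", "Hispanic", "Other"]  # ref White
REGION_LEVELS = ["Northeast", "Midwest", "South"]  # ref West
STAGE_LEVELS = ["II", "III"]  # ref I
GRADE_LEVELS = ["moderate", "poor", "undifferentiated"]  # ref well
GAGNE_LEVELS = ["1", "2", "3+"]  # ref <=0


@dataclass
class PredictorDesign:
    y: pd.Series  # 1 = nonresilient
    X: pd.DataFrame  # includes const
    row_ids: pd.Series


def _gagne_cat_le0(cat: str) -> str:
    return "<=0" if cat in ("<0", "0") else cat


def build_design(
    cohort: pd.DataFrame,
    cluster_labels: pd.Series,
    baseline_flags: pd.DataFrame,
) -> PredictorDesign:
    """Assemble the outcome and reference-coded design matrix.

    ``cluster_labels`` maps row_id to a category string (robust /
    resilient / nonresilient); rows without a label (persons dropped from
    clustering for short follow-up) are excluded.  ``baseline_flags`` is a
    row_id-indexed 0/1 frame over the 20 frailty indicators at the index
    date.
    """
    df = cohort.set_index("row_id")
    labelled = cluster_labels.dropna()
    df = df.loc[df.index.intersection(labelled.index)]
    y = labelled.loc[df.index].map(
        {"robust": 0, "resilient": 0, "nonresilient": 1}
    )
    if y.isna().any():
        bad = sorted(set(labelled.loc[df.index][y.isna()]))
        raise ValueError(f"unknown cluster categories: {bad}")

    cols: dict[str, np.ndarray] = {"const": np.ones(len(df))}
    cols["age_minus_65"] = df["age"].astype(float).to_numpy() - 65.0

    def dummies(series: pd.Series, levels: list[str], prefix: str, known: set):
        seen = set(map(str, series.dropna().unique()))
        unexpected = seen - known
        if unexpected:
            raise ValueError(f"unseen {prefix} levels: {sorted(unexpected)}")
        for lev in levels:
            cols[f"{prefix}[{lev}]"] = (series.astype(str) == lev).astype(float).to_numpy()

    race = df["race_ethnicity"].astype(str).replace(RACE_COLLAPSE)
    dummies(race, RACE_LEVELS, "race", {"White", "missing", *RACE_LEVELS})
    dummies(df["region"].astype(str), REGION_LEVELS, "region",
            {"West", *REGION_LEVELS})
    dummies(df["stage"].astype(str), STAGE_LEVELS, "stage", {"I", *STAGE_LEVELS})
    cols["mastectomy"] = (df["surgery_type"].astype(str) == "mastectomy").astype(float).to_numpy()
    dummies(df["grade"].astype(str), GRADE_LEVELS, "grade",
            {"well", "missing", *GRADE_LEVELS})
    gagne = df["gagne_category"].astype(str).map(_gagne_cat_le0)
    dummies(gagne, GAGNE_LEVELS, "gagne", {"<=0", *GAGNE_LEVELS})
    cols["flu_vaccine"] = df["flu_vaccine_flag"].astype(float).to_numpy()
    flags = baseline_flags.reindex(df.index)
    for ind in FRAILTY_INDICATORS:
        cols[ind] = flags[ind].astype(float).to_numpy()

    X = pd.DataFrame(cols, index=df.index)
    return PredictorDesign(y=y.astype(int), X=X, row_ids=pd.Series(df.index))


def fit_nonresilience(
    design: PredictorDesign,
    drop_constant: bool = True,
    ridge_alpha: float | None = None,
) -> pd.DataFrame:
    """Maximum-likelihood logistic fit; returns an OR table.

    Columns constant in the design are dropped (they cannot be estimated).
    Perfect separation raises :class:`SeparationError`; passing
    ``ridge_alpha`` refits with an L2 penalty instead (no CIs reported for
    penalized terms).
    """
    y = design.y.to_numpy()
    if len(set(y)) < 2:
        raise ValueError("both outcome classes must be present")
    X = design.X
    if drop_constant:
        keep = ["const"] + [c for c in X.columns if c != "const" and X[c].nunique() > 1]
        X = X[keep]
    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=False, maxiter=200)
        eta = np.asarray(res.predict(X, which="linear"))
        if not res.mle_retvals.get("converged", False) or np.abs(eta).max() > 25:
            raise np.linalg.LinAlgError
        params, bse = res.params, res.bse
        penalized = False
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        if ridge_alpha is None:
            raise SeparationError(
                "separation in nonresilience model; refit with ridge_alpha "
                "or coarsen covariates"
            )
        res = model.fit_regularized(
            alpha=ridge_alpha, L1_wt=0.0, disp=False, maxiter=500
        )
        params = res.params
        bse = pd.Series(np.nan, index=params.index)
        penalized = True
    zcrit = 1.959963984540054
    out = pd.DataFrame({
        "term": params.index,
        "estimate": params.to_numpy(),
        "OR": np.exp(params.to_numpy()),
        "ci_low": np.exp(params.to_numpy() - zcrit * np.asarray(bse)),
        "ci_high": np.exp(params.to_numpy() + zcrit * np.asarray(bse)),
    })
    out.attrs["penalized"] = penalized
    return out
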