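"""Three-timepoint weighted GEE benchmark of frailty change.

Frailty is scored at the index date (T1), 4 months (T2 = day 120) and
10 months (T3 = day 300) post-index.  The marginal mean model is

    E[Y] = b0 + b1*chemo + b2*1[T2] + b3*1[T3] + b4*chemo*1[T2] + b5*chemo*1[T3]

fit by GEE with a gamma variance function, identity link, AR(1) working
correlation over the three occasions (treated as equally spaced), each
cohort row as its own cluster, observation weights equal to the combined
SMR x attrition weight, and robust (sandwich) confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .claims_core import DEFAULT_LOOKBACK_DAYS, TIMEPOINT_OFFSETS, CodeMap, TableBundle
from .frailty_index import (
    FrailtyModel,
    indicator_matrix,
    observation_end,
    score_matrix,
)
from .cohort_builder import gagne_frame

TERM_LABELS = ["Intercept", "Cohort[chemo]", "T2", "T3", "T2*chemo", "T3*chemo"]

CELL_COMBINATIONS = {
    # (arm, timepoint) -> coefficient loadings on (b0..b5)
    ("comparator", "T1"): (1, 0, 0, 0, 0, 0),
    ("comparator", "T2"): (1, 0, 1, 0, 0, 0),
    ("comparator", "T3"): (1, 0, 0, 1, 0, 0),
    ("chemo", "T1"): (1, 1, 0, 0, 0, 0),
    ("chemo", "T2"): (1, 1, 1, 0, 1, 0),
    ("chemo", "T3"): (1, 1, 0, 1, 0, 1),
}


def build_panel(
    cohort: pd.DataFrame,
    bundle: TableBundle,
    model: FrailtyModel | None = None,
    codemap: CodeMap | None = None,
    timepoints: dict | None = None,
    lookback_days: int = DEFAULT_LOOKBACK_DAYS,
) -> pd.DataFrame:
    """Long panel with one row per cohort row x timepoint.

    Carries the frailty score (NaN when the row is no longer observed),
    the time-varying comorbidity score, baseline covariates, and the
    period-event flags needed by the attrition models.  Anchors are at
    +0/+120/+300 days from each row's (inherited) index date.
    """
    model = model or FrailtyModel()
    codemap = codemap or CodeMap.synthetic_identity()
    timepoints = dict(timepoints or TIMEPOINT_OFFSETS)
    cohort = cohort.copy().reset_index(drop=True)
    if "row_id" not in cohort.columns:
        cohort["row_id"] = np.arange(len(cohort))

    pairs = cohort[["person_id", "index_date"]].drop_duplicates()
    obs = observation_end(bundle.persons, bundle.enrollment, pairs)
    death = bundle.persons.set_index("person_id")["death_date"]

    tps = list(timepoints)
    long = cohort.loc[cohort.index.repeat(len(tps)), [
        "row_id", "person_id", "arm", "index_date", "age", "race_ethnicity",
        "region", "flu_vaccine_flag",
    ]].reset_index(drop=True)
    long["timepoint"] = np.tile(tps, len(cohort))
    long["offset_days"] = long["timepoint"].map(timepoints)
    long["anchor"] = long["index_date"] + pd.to_timedelta(long["offset_days"], unit="D")
    long = long.merge(obs, on=["person_id", "index_date"], how="left")
    long["observed"] = long["anchor"] <= long["observation_end"]

    # scores and comorbidity only where observed
    sub = long[long["observed"]].copy()
    af = pd.DataFrame({
        "row_id": np.arange(len(sub)),
        "person_id": sub["person_id"].to_numpy(),
        "anchor": sub["anchor"].to_numpy(),
    })
    flags = indicator_matrix(bundle.claims, af, lookback_days, codemap)
    demo = pd.DataFrame({
        "age_at_anchor": pd.DatetimeIndex(sub["anchor"]).year.to_numpy()
        - sub["person_id"].map(
            bundle.persons.set_index("person_id")["birth_year"]
        ).to_numpy(),
        "race_ethnicity": sub["race_ethnicity"].to_numpy(),
    }, index=flags.index)
    sub_scores = score_matrix(model, flags, demo).to_numpy()
    sub_gagne = gagne_frame(bundle.claims, af, codemap=codemap).to_numpy()
    long["score"] = np.nan
    long.loc[sub.index, "score"] = sub_scores
    long["gagne_score"] = np.nan
    long.loc[sub.index, "gagne_score"] = sub_gagne
    long["lagged_frailty"] = long["score"]

    # period events: person observed at the period start but not at its end
    death_dates = long["person_id"].map(death)
    order = {tp: i for i, tp in enumerate(tps)}
    wide_obs = long.pivot_table(
        index="row_id", columns="timepoint", values="observed", aggfunc="first"
    )
    wide_anchor = long.pivot_table(
        index="row_id", columns="timepoint", values="anchor", aggfunc="first"
    )
    long["death_in_period"] = False
    long["disenroll_in_period"] = False
    for start, end in zip(tps[:-1], tps[1:]):
        obs_end_tp = long["row_id"].map(wide_obs[end])
        anchor_end = long["row_id"].map(wide_anchor[end])
        here = long["timepoint"] == start
        lost = here & long["observed"] & ~obs_end_tp.astype(bool)
        died = lost & death_dates.notna() & (death_dates <= anchor_end)
        long.loc[died, "death_in_period"] = True
        long.loc[lost & ~died, "disenroll_in_period"] = True
    _ = order
    return long


@dataclass
class GEEFit:
    """Coefficient table in the benchmark layout plus fit metadata."""

    table: pd.DataFrame  # index TERM_LABELS; estimate, ci_low, ci_high, se
    result: object
    scale: float
    working_correlation: float
    cov_type: str = "robust"

    @property
    def params(self) -> np.ndarray:
        return self.table["estimate"].to_numpy()


class _DegenerateResult:
    """Stand-in result for an exactly-fit panel (zero residual variance)."""

    def __init__(self, p: int):
        self._p = p

    def cov_params(self):
        return np.zeros((self._p, self._p))


def _design(panel: pd.DataFrame) -> np.ndarray:
    arm = (panel["arm"] == "chemo").astype(float).to_numpy()
    t2 = (panel["timepoint"] == "T2").astype(float).to_numpy()
    t3 = (panel["timepoint"] == "T3").astype(float).to_numpy()
    return np.column_stack([
        np.ones(len(panel)), arm, t2, t3, arm * t2, arm * t3,
    ])


def fit_gee(panel: pd.DataFrame, weight_col: str | None = "combined_weight") -> GEEFit:
    """Weighted gamma/identity/AR(1) GEE of the benchmark contrast model."""
    data = panel[panel["observed"] & panel["score"].notna()].copy()
    if not len(data):
        raise ValueError("panel has no observed rows")
    if "row_id" not in data.columns:
        data["row_id"] = data["person_id"]
    weights = None
    if weight_col is not None and weight_col in data.columns:
        weights = data[weight_col].to_numpy()
        if (weights < 0).any():
            raise ValueError("weights must be nonnegative")
    X = _design(data)
    y = data["score"].to_numpy()
    occasion = data["timepoint"].map({"T1": 0, "T2": 1, "T3": 2}).to_numpy()

    # degenerate exactly-fit panel (e.g. constant outcome): the estimating
    # equations are solved by least squares with zero residual variance
    beta_ls, *_ = np.linalg.lstsq(X, y, rcond=None)
    if np.max(np.abs(y - X @ beta_ls)) < 1e-12 * max(1.0, np.abs(y).max()):
        zeros = np.zeros(X.shape[1])
        table = pd.DataFrame(
            {"estimate": beta_ls, "se": zeros, "ci_low": beta_ls, "ci_high": beta_ls},
            index=TERM_LABELS,
        )
        return GEEFit(table=table, result=_DegenerateResult(X.shape[1]),
                      scale=0.0, working_correlation=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # identity link with Gamma is intended
        family = sm.families.Gamma(link=sm.families.links.Identity())
        model = sm.GEE(
            y, X,
            groups=data["row_id"].to_numpy(),
            time=occasion,
            family=family,
            cov_struct=sm.cov_struct.Autoregressive(grid=True),
            weights=weights,
        )
        res = model.fit(maxiter=100)
    params = np.asarray(res.params)
    if not np.all(np.isfinite(params)):
        raise RuntimeError(f"GEE failed to converge; parameter trace: {params}")
    fitted = X @ params
    if (fitted <= 0).any():
        warnings.warn(
            "negative fitted means under the identity link; estimates kept, "
            "interpret the gamma variance function with care"
        )
    se = np.asarray(res.bse)
    zcrit = 1.959963984540054
    table = pd.DataFrame(
        {
            "estimate": params,
            "se": se,
            "ci_low": params - zcrit * se,
            "ci_high": params + zcrit * se,
        },
        index=TERM_LABELS,
    )
    dep = res.cov_struct.dep_params
    rho = float(np.atleast_1d(dep)[0])
    return GEEFit(
        table=table, result=res, scale=float(res.scale), working_correlation=rho
    )


def marginal_means(fit: GEEFit) -> pd.DataFrame:
    """Arm x timepoint model-based means with delta-method CIs."""
    beta = fit.params
    cov = np.asarray(fit.result.cov_params())
    zcrit = 1.959963984540054
    rows = []
    for (arm, tp), load in CELL_COMBINATIONS.items():
        L = np.asarray(load, dtype=float)
        mean = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        rows.append((arm, tp, mean, mean - zcrit * se, mean + zcrit * se))
    return pd.DataFrame(
        rows, columns=["arm", "timepoint", "mean", "ci_low", "ci_high"]
    ).sort_values(["arm", "timepoint"]).reset_index(drop=True)
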