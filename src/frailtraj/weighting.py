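"""Cohort standardization and attrition weights.

Two weight families multiply into the observation weights of the benchmark
marginal model:

* **SMR weights** standardize the comparator covariate distribution to the
  chemotherapy cohort: treated weight 1, comparator weight ``ps/(1-ps)``
  (the propensity odds), with optional percentile truncation.
* **Inverse probability of attrition weights (IPAW)** address informative
  loss to death and fee-for-service disenrollment between follow-up
  timepoints: discrete-time (pooled logistic) hazard models per cause give
  per-period retention probabilities whose cumulative inverse product
  upweights persons who remain under observation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

REFERENCE_LEVELS = {
    "race_ethnicity": "White",
    "region": "West",
    "gagne_category": "0",
    "stage": "I",
    "grade": "well",
    "surgery_type": "BCT",
}

DEFAULT_PROPENSITY_COVARIATES = [
    "age", "race_ethnicity", "region", "gagne_category", "flu_vaccine_flag",
]

#: Timepoint successor map defining the attrition periods (T1,T2] and (T2,T3].
PERIODS = [("T1", "T2"), ("T2", "T3")]


class SeparationError(RuntimeError):
    """Perfect separation in a logistic fit; coarsen covariates."""


def build_design_matrix(
    df: pd.DataFrame, covariates: list[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Design matrix with an intercept; categoricals are dummy-coded against
    the fixed reference levels.  Constant columns are dropped with a warning.
    Returns (X, dropped_columns)."""
    cols = {"const": np.ones(len(df))}
    for cov in covariates:
        s = df[cov]
        if s.dtype == bool or pd.api.types.is_numeric_dtype(s):
            cols[cov] = s.astype(float).to_numpy()
        else:
            levels = sorted(map(str, s.dropna().unique()))
            ref = REFERENCE_LEVELS.get(cov)
            if ref is None or ref not in levels:
                ref = levels[0]
            for lev in levels:
                if lev == ref:
                    continue
                cols[f"{cov}[{lev}]"] = (s.astype(str) == lev).astype(float).to_numpy()
    X = pd.DataFrame(cols, index=df.index)
    dropped = [c for c in X.columns if c != "const" and X[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping constant covariate columns: {dropped}")
        X = X.drop(columns=dropped)
    return X, dropped


def _fit_logistic(y: np.ndarray, X: pd.DataFrame) -> sm.GLM:
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=200, tol=1e-12)
    eta = np.asarray(res.predict(X, which="linear"))
    if not res.converged or np.abs(eta).max() > 30:
        raise SeparationError(
            "logistic fit did not converge to interior probabilities; "
            "likely perfect separation — coarsen covariates"
        )
    return res


@dataclass
class PropensityFit:
    """Arm-membership model P(arm = chemo | baseline covariates)."""

    result: object
    ps: pd.Series  # fitted probabilities indexed like the cohort
    covariates: list[str]
    dropped: list[str] = field(default_factory=list)
    #: sparse categorical levels merged into the reference before fitting
    recodes: dict = field(default_factory=dict)

    @property
    def coefficients(self) -> pd.Series:
        return self.result.params


def fit_propensity(
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    min_cell: int = 5,
) -> PropensityFit:
    """Logistic regression of chemo-arm membership on baseline covariates.

    Categorical levels with fewer than ``min_cell`` members in either arm
    are merged into the reference level first: such cells carry almost no
    information and routinely quasi-separate the fit.
    """
    covariates = list(covariates or DEFAULT_PROPENSITY_COVARIATES)
    arms = set(cohort["arm"])
    if not {"chemo", "comparator"} <= arms:
        raise ValueError("cohort must contain both arms")
    cohort = cohort.copy()
    recodes: dict = {}
    for cov in covariates:
        s = cohort[cov]
        if s.dtype == bool or pd.api.types.is_numeric_dtype(s):
            continue
        counts = pd.crosstab(s.astype(str), cohort["arm"])
        sparse = counts.index[counts.min(axis=1) < min_cell]
        if len(sparse):
            ref = REFERENCE_LEVELS.get(cov, counts.sum(axis=1).idxmax())
            warnings.warn(
                f"merging sparse {cov} levels {list(sparse)} into {ref!r}"
            )
            recodes[cov] = {lev: ref for lev in sparse}
            cohort[cov] = s.astype(str).where(~s.astype(str).isin(sparse), ref)
    y = (cohort["arm"] == "chemo").astype(float).to_numpy()
    X, dropped = build_design_matrix(cohort, covariates)
    res = _fit_logistic(y, X)
    ps = pd.Series(np.asarray(res.predict(X)), index=cohort.index, name="ps")
    return PropensityFit(result=res, ps=ps, covariates=covariates,
                         dropped=dropped, recodes=recodes)


def apply_propensity_recodes(cohort: pd.DataFrame, fit: PropensityFit) -> pd.DataFrame:
    """Cohort with the fit's sparse-level merges applied, i.e. the covariate
    coding the propensity model actually balanced."""
    out = cohort.copy()
    for cov, mapping in fit.recodes.items():
        out[cov] = out[cov].astype(str).replace(mapping)
    return out


def smr_weights(
    fit: PropensityFit,
    cohort: pd.DataFrame,
    truncate_percentile: float | None = 99.0,
) -> pd.Series:
    """Per-row SMR weight: 1 for chemo rows, propensity odds for comparators.

    Comparator weights above the configured percentile (of comparator
    weights) are capped; extrema before/after truncation are recorded in
    ``result.attrs``.
    """
    ps = fit.ps
    if ((ps <= 0) | (ps >= 1)).any():
        raise ValueError("propensity scores must lie in (0, 1)")
    w = pd.Series(1.0, index=cohort.index, name="smr_weight")
    comp = cohort["arm"] == "comparator"
    w[comp] = (ps[comp] / (1.0 - ps[comp])).to_numpy()
    pre_max = float(w[comp].max()) if comp.any() else 1.0
    if truncate_percentile is not None and comp.any():
        cap = float(np.percentile(w[comp], truncate_percentile))
        w[comp] = np.minimum(w[comp], cap)
    w.attrs["max_weight_pre_truncation"] = pre_max
    w.attrs["max_weight_post_truncation"] = float(w[comp].max()) if comp.any() else 1.0
    w.attrs["truncate_percentile"] = truncate_percentile
    return w


# ---------------------------------------------------------------------------
# Attrition
# ---------------------------------------------------------------------------

# Continuous/binary summaries only: attrition events are rare, and sparse
# categorical cells (race x few deaths) quasi-separate the pooled logistic.
DEFAULT_ATTRITION_COVARIATES = [
    "age", "flu_vaccine_flag", "gagne_score", "lagged_frailty",
]


@dataclass
class AttritionFit:
    cause: str
    result: object | None  # None when the cause has zero events
    covariates: list[str]
    n_events: int
    risk_table: pd.DataFrame  # person-period rows with predicted event prob


def make_attrition_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Person-period risk table from the three-timepoint long panel.

    ``panel`` needs one row per (row_id, timepoint) with ``observed``,
    ``death_in_period`` / ``disenroll_in_period`` flags attached by the
    panel builder, plus covariates.  A row contributes period j only if
    observed at its start; a competing event removes later contributions.
    """
    rows = []
    wide_obs = panel.pivot_table(
        index="row_id", columns="timepoint", values="observed", aggfunc="first"
    )
    by_row = {rid: g.set_index("timepoint") for rid, g in panel.groupby("row_id")}
    for rid, g in by_row.items():
        failed = False
        for start, end in PERIODS:
            if failed or start not in g.index or not bool(g.loc[start, "observed"]):
                break
            death = bool(g.loc[start, "death_in_period"])
            dis = bool(g.loc[start, "disenroll_in_period"]) and not death
            rec = g.loc[start].to_dict()
            rec.update({
                "row_id": rid, "period": f"{start}->{end}",
                "event_death": death, "event_disenroll": dis,
            })
            rows.append(rec)
            if death or dis:
                failed = True
    out = pd.DataFrame(rows)
    _ = wide_obs  # pivot kept for future diagnostics
    return out


def fit_attrition_models(
    risk_table: pd.DataFrame,
    cause: str,
    covariates: list[str] | None = None,
) -> AttritionFit:
    """Pooled logistic (discrete-time hazard) model for one attrition cause.

    Period enters as an indicator; persons who already failed from the
    competing cause are absent from later periods by construction of the
    risk table.  With zero events the predicted event probability is 0
    (retention 1) and a warning is issued.
    """
    if cause not in ("death", "disenrollment"):
        raise ValueError("cause must be 'death' or 'disenrollment'")
    covariates = list(covariates or DEFAULT_ATTRITION_COVARIATES)
    covariates = [c for c in covariates if c in risk_table.columns]
    event_col = "event_death" if cause == "death" else "event_disenroll"
    y = risk_table[event_col].astype(float).to_numpy()
    tbl = risk_table.copy()
    n_events = int(y.sum())
    if n_events == 0:
        warnings.warn(f"no {cause} events; retention probability fixed at 1")
        tbl["event_prob"] = 0.0
        return AttritionFit(cause, None, covariates, 0, tbl)
    X, _ = build_design_matrix(tbl, covariates)
    for per in sorted(tbl["period"].unique())[1:]:
        X[f"period[{per}]"] = (tbl["period"] == per).astype(float).to_numpy()
    res = _fit_logistic(y, X)
    tbl["event_prob"] = np.asarray(res.predict(X))
    return AttritionFit(cause, res, covariates, n_events, tbl)


def ipaw(
    death_fit: AttritionFit,
    disenroll_fit: AttritionFit,
    panel: pd.DataFrame,
    truncate_percentile: float | None = 99.0,
) -> pd.Series:
    """Inverse-probability-of-attrition weight per observed (row, timepoint).

    For a person observed at timepoint k the weight is the inverse product,
    over periods up to k, of the predicted probabilities of remaining free
    of each attrition cause.  T1 weights are 1.
    """
    ret = {}
    for fit in (death_fit, disenroll_fit):
        r = fit.risk_table.set_index(["row_id", "period"])["event_prob"]
        if (r >= 1.0).any():
            raise ValueError(
                "predicted retention probability 0; raise truncation or "
                "coarsen the attrition model"
            )
        ret[fit.cause] = 1.0 - r
    w = pd.Series(1.0, index=panel.index, name="ipaw_weight")
    cum = {}
    for rid in panel["row_id"].unique():
        cum[rid] = 1.0
    for (start, end) in PERIODS:
        per = f"{start}->{end}"
        for rid in list(cum):
            key = (rid, per)
            factor = 1.0
            present = False
            for cause in ret:
                if key in ret[cause].index:
                    factor *= float(ret[cause].loc[key])
                    present = True
            if present:
                cum[rid] = cum[rid] * factor
        sel = (panel["timepoint"] == end) & panel["observed"]
        w[sel] = panel.loc[sel, "row_id"].map(
            {rid: 1.0 / c for rid, c in cum.items()}
        ).to_numpy()
    if truncate_percentile is not None:
        tail = w[panel["timepoint"] != "T1"]
        if len(tail):
            cap = float(np.percentile(tail, truncate_percentile))
            w = np.minimum(w, cap)
            w = pd.Series(w, index=panel.index, name="ipaw_weight")
    return w


def balance_table(
    cohort: pd.DataFrame,
    weights: pd.Series,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Standardized mean differences between arms, unweighted vs weighted.

    Categorical covariates are expanded to one row per level; SMD =
    (chemo mean - weighted comparator mean) / pooled unweighted SD.
    """
    covariates = list(covariates or DEFAULT_PROPENSITY_COVARIATES)
    chemo = cohort["arm"] == "chemo"
    comp = ~chemo
    rows = []
    for cov in covariates:
        s = cohort[cov]
        if s.dtype == bool or pd.api.types.is_numeric_dtype(s):
            columns = {cov: s.astype(float)}
        else:
            columns = {
                f"{cov}={lev}": (s.astype(str) == str(lev)).astype(float)
                for lev in sorted(map(str, s.dropna().unique()))
            }
        for name, x in columns.items():
            m1 = x[chemo].mean()
            sd = np.sqrt((x[chemo].var(ddof=1) + x[comp].var(ddof=1)) / 2.0)
            m0_raw = x[comp].mean()
            wc = weights[comp]
            m0_w = np.average(x[comp], weights=wc)
            smd_pre = 0.0 if sd == 0 else (m1 - m0_raw) / sd
            smd_post = 0.0 if sd == 0 else (m1 - m0_w) / sd
            rows.append((name, m1, m0_raw, m0_w, smd_pre, smd_post))
    return pd.DataFrame(
        rows,
        columns=[
            "covariate", "chemo_mean", "comparator_mean",
            "comparator_mean_weighted", "smd_unweighted", "smd_weighted",
        ],
    )
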