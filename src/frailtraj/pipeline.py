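"""End-to-end orchestration of the benchmark and trajectory analyses.

These functions wire the stage modules together in the order the study
design requires: simulate (or load) tables, build the eligibility-screened
chemotherapy cohort, match noncancer comparators, score frailty, construct
SMR and attrition weights, fit the weighted GEE benchmark, and cluster the
chemo-arm monthly trajectories with nonresilience prediction.  The CLI and
the acceptance script are thin wrappers over this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .claims_core import TIMEPOINT_OFFSETS, CodeMap, TableBundle
from .cohort_builder import build_chemo_cohort, match_comparators
from .frailty_index import FrailtyModel, indicator_matrix, score_series_frame
from .benchmark_gee import GEEFit, build_panel, fit_gee, marginal_means
from .synthetic_data import SimConfig, generate_population
from .trajectory_clustering import (
    ClusterSolution,
    LabelRules,
    build_trajectories,
    label_clusters,
    mean_assigned_posterior,
    posterior_probs,
    select_k,
)
from .predictors import build_design, fit_nonresilience
from .weighting import SeparationError
from .weighting import (
    apply_propensity_recodes,
    balance_table,
    fit_attrition_models,
    fit_propensity,
    ipaw,
    make_attrition_panel,
    smr_weights,
)


@dataclass
class BenchmarkResult:
    cohort: pd.DataFrame
    ledger: pd.DataFrame
    panel: pd.DataFrame
    gee: GEEFit
    means: pd.DataFrame
    balance: pd.DataFrame
    weights: pd.DataFrame


@dataclass
class TrajectoryResult:
    series: pd.DataFrame
    matrix: np.ndarray
    roster: pd.DataFrame
    solution: ClusterSolution
    criterion_table: pd.DataFrame
    labels: dict
    shares: dict
    or_table: pd.DataFrame | None


def build_matched_cohort(
    bundle: TableBundle,
    ratio: int = 5,
    seed: int = 0,
    codemap: CodeMap | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    chemo, ledger = build_chemo_cohort(bundle, codemap=codemap)
    cohort = match_comparators(chemo, bundle, ratio=ratio, seed=seed, codemap=codemap)
    return cohort, ledger


def run_benchmark(
    bundle: TableBundle,
    cohort: pd.DataFrame | None = None,
    ledger: pd.DataFrame | None = None,
    model: FrailtyModel | None = None,
    codemap: CodeMap | None = None,
    match_seed: int = 0,
    ratio: int = 5,
) -> BenchmarkResult:
    """Matched cohort -> scores -> SMR + attrition weights -> weighted GEE."""
    model = model or FrailtyModel()
    if cohort is None:
        cohort, ledger = build_matched_cohort(bundle, ratio=ratio, seed=match_seed,
                                              codemap=codemap)
    ps_fit = fit_propensity(cohort)
    smr = smr_weights(ps_fit, cohort)
    cohort = cohort.assign(smr_weight=smr.to_numpy())

    panel = build_panel(cohort, bundle, model=model, codemap=codemap)
    risk = make_attrition_panel(panel)
    death_fit = fit_attrition_models(risk, "death")
    dis_fit = fit_attrition_models(risk, "disenrollment")
    w_att = ipaw(death_fit, dis_fit, panel)
    panel = panel.assign(ipaw_weight=w_att.to_numpy())
    panel["smr_weight"] = panel["row_id"].map(
        cohort.set_index("row_id")["smr_weight"]
    )
    panel["combined_weight"] = panel["smr_weight"] * panel["ipaw_weight"]

    gee = fit_gee(panel, weight_col="combined_weight")
    means = marginal_means(gee)
    bal = balance_table(apply_propensity_recodes(cohort, ps_fit), smr)
    weights = panel[["row_id", "person_id", "arm", "timepoint",
                     "smr_weight", "ipaw_weight", "combined_weight"]].copy()
    return BenchmarkResult(
        cohort=cohort,
        ledger=ledger if ledger is not None else pd.DataFrame(),
        panel=panel, gee=gee, means=means, balance=bal, weights=weights,
    )


def run_trajectories(
    bundle: TableBundle,
    chemo_cohort: pd.DataFrame,
    model: FrailtyModel | None = None,
    codemap: CodeMap | None = None,
    k_range=range(2, 9),
    n_starts: int = 20,
    seed: int = 0,
    rules: LabelRules | None = None,
    fit_predictors: bool = True,
) -> TrajectoryResult:
    """Monthly chemo-arm trajectories -> K-means -> labels -> predictors."""
    model = model or FrailtyModel()
    chemo = chemo_cohort[chemo_cohort["arm"] == "chemo"].copy().reset_index(drop=True)
    chemo["row_id"] = np.arange(len(chemo))
    series = score_series_frame(
        bundle.claims, bundle.persons, chemo, bundle.enrollment,
        model=model, codemap=codemap,
    )
    X, roster = build_trajectories(series)
    solution, crit_table = select_k(X, k_range=k_range, n_starts=n_starts, seed=seed)
    posterior_probs(X, solution)
    labels = label_clusters(solution, rules)

    sizes = np.bincount(solution.assignment, minlength=solution.k)
    shares = {"robust": 0.0, "resilient": 0.0, "nonresilient": 0.0}
    for c, lab in labels.items():
        shares[lab["category"]] += sizes[c] / sizes.sum()

    or_table = None
    if fit_predictors:
        label_by_row = pd.Series(
            [labels[c]["category"] for c in solution.assignment],
            index=roster["row_id"].to_numpy(),
        )
        af = chemo[["row_id", "person_id", "index_date"]].rename(
            columns={"index_date": "anchor"}
        )
        flags = indicator_matrix(bundle.claims, af, codemap=codemap)
        design = build_design(chemo, label_by_row, flags)
        if design.y.nunique() == 2:
            try:
                or_table = fit_nonresilience(design)
            except SeparationError:
                # sparse indicator cells at moderate n; ridge keeps the
                # point estimates interpretable (no Wald CIs reported)
                or_table = fit_nonresilience(design, ridge_alpha=1.0)
    return TrajectoryResult(
        series=series, matrix=X, roster=roster, solution=solution,
        criterion_table=crit_table, labels=labels, shares=shares,
        or_table=or_table,
    )


def run_full_study(
    config: SimConfig | None = None,
    seed: int | None = None,
    k_range=range(2, 9),
    n_starts: int = 10,
) -> dict:
    """Simulate and run both analyses; returns a dict of all artifacts."""
    config = config or SimConfig()
    if seed is not None:
        config = SimConfig(**{**config.__dict__, "seed": seed})
    bundle, truth = generate_population(config)
    cohort, ledger = build_matched_cohort(bundle, seed=config.seed + 1)
    bench = run_benchmark(bundle, cohort=cohort, ledger=ledger)
    traj = run_trajectories(
        bundle, cohort, k_range=k_range, n_starts=n_starts, seed=config.seed + 2
    )
    return {
        "config": config, "bundle": bundle, "truth": truth,
        "cohort": cohort, "ledger": ledger,
        "benchmark": bench, "trajectories": traj,
    }
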