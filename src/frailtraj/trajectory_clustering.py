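"""Longitudinal K-means clustering of monthly frailty trajectories.

Each person contributes a 13-anchor monthly frailty series (days 0-360 in
30-day steps) with monotone dropout: once a person dies or disenrolls the
rest of the series is missing, so missingness is always a suffix.  Persons
with fewer than three observed anchors are dropped.

Clustering is Lloyd-style K-means under a missing-aware squared distance

    d^2(a, b) = (T / T_obs) * sum_{t observed in both} (a_t - b_t)^2,

the usual available-case rescaling for longitudinal K-means.  Cluster
centers are anchor-wise weighted means (weights T/T_obs so the update step
exactly minimizes the within-cluster sum under this metric, making the
objective monotone across iterations).  The number of clusters is chosen
over a 2-8 range by a Calinski-Harabasz-type criterion

    C = [B/(k-1)] / [W/(n-k)]

with between- and within-cluster dispersion computed under the same
missing-aware distance.  Posterior membership probabilities use a Gaussian
kernel with the pooled within-cluster variance, and clusters are labelled
robust / resilient / nonresilient from the shape of their center
trajectories by an explicit, configurable rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

N_ANCHORS = 13


class TrajectoryError(ValueError):
    pass


def build_trajectories(
    score_frame: pd.DataFrame,
    min_observed: int = 3,
    n_anchors: int = N_ANCHORS,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Person x anchor matrix (NaN suffix for dropout) from a score series.

    ``score_frame`` is the long output of the monthly scorer (columns
    ``row_id``, ``month``, ``score``).  Persons with fewer than
    ``min_observed`` anchors are dropped; non-suffix missingness is an
    error because the series contract guarantees monotone dropout.
    Returns ``(matrix, roster)`` where roster maps matrix rows to row_ids
    and records observed-anchor counts (dropped count in
    ``roster.attrs["n_dropped"]``).
    """
    wide = score_frame.pivot_table(
        index="row_id", columns="month", values="score", aggfunc="first"
    ).reindex(columns=range(n_anchors))
    X = wide.to_numpy(dtype=float)
    observed = ~np.isnan(X)
    # suffix rule: no observed anchor after the first missing one
    first_missing = np.where(
        observed.all(axis=1), n_anchors, (~observed).argmax(axis=1)
    )
    for i, fm in enumerate(first_missing):
        if observed[i, fm:].any():
            raise TrajectoryError(
                f"non-suffix missingness for row_id {wide.index[i]}"
            )
    counts = observed.sum(axis=1)
    keep = counts >= min_observed
    roster = pd.DataFrame(
        {"row_id": wide.index[keep], "n_observed": counts[keep]}
    ).reset_index(drop=True)
    roster.attrs["n_dropped"] = int((~keep).sum())
    return X[keep], roster


def traj_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Missing-aware trajectory distance (scalar form)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    both = ~np.isnan(a) & ~np.isnan(b)
    t_obs = int(both.sum())
    if t_obs == 0:
        raise TrajectoryError("trajectories share no observed anchor")
    d2 = (len(a) / t_obs) * float(((a[both] - b[both]) ** 2).sum())
    return float(np.sqrt(d2))


def _sq_dist_to_centers(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """(n, k) squared distances; centers must be complete."""
    diff = X[:, None, :] - centers[None, :, :]
    ssq = np.nansum(diff ** 2, axis=2)
    t_obs = (~np.isnan(X)).sum(axis=1)
    return ssq * (X.shape[1] / t_obs)[:, None]


def _update_centers(
    X: np.ndarray, assign: np.ndarray, k: int, fallback: np.ndarray
) -> np.ndarray:
    """Anchor-wise weighted means (weights T/T_obs); anchors with no
    observed member fall back to the global mean trajectory."""
    T = X.shape[1]
    w = (T / (~np.isnan(X)).sum(axis=1)).astype(float)
    centers = np.empty((k, T))
    for c in range(k):
        members = X[assign == c]
        if not len(members):
            centers[c] = fallback
            continue
        wm = w[assign == c][:, None] * ~np.isnan(members)
        vals = np.where(np.isnan(members), 0.0, members)
        denom = wm.sum(axis=0)
        num = (vals * w[assign == c][:, None]).sum(axis=0)
        centers[c] = np.where(denom > 0, num / np.maximum(denom, 1e-300), fallback)
    return centers


def _global_mean(X: np.ndarray) -> np.ndarray:
    """Weighted anchor-wise mean trajectory (same weights as centers)."""
    T = X.shape[1]
    w = (T / (~np.isnan(X)).sum(axis=1)).astype(float)[:, None]
    obs = ~np.isnan(X)
    vals = np.where(obs, X, 0.0)
    denom = (w * obs).sum(axis=0)
    mean = (vals * w).sum(axis=0) / np.maximum(denom, 1e-300)
    # an anchor observed by nobody has no defined mean; carry forward
    missing = denom <= 0
    if missing.any():
        last = mean[~missing][-1] if (~missing).any() else 0.0
        mean[missing] = last
    return mean


@dataclass
class ClusterSolution:
    k: int
    assignment: np.ndarray
    centers: np.ndarray
    inertia: float  # within-cluster sum of squared distances W
    iterations: int
    best_start: int
    criterion: float = np.nan
    criterion_flag: str = ""
    posterior: np.ndarray | None = None
    repairs: int = 0
    labels: dict = field(default_factory=dict)


def _kpp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy k-means++ seeding under the missing-aware distance.

    Each new seed is chosen among several D^2-sampled candidates as the one
    minimizing the total potential; this reliably seeds small distant
    groups without being captured by single noisy truncated trajectories.
    """
    n = len(X)
    gm = _global_mean(X)
    filled = np.where(np.isnan(X), gm, X)
    n_cand = 2 + int(np.log(max(k, 2)) * 2)
    idx = [int(rng.integers(n))]
    d2 = _sq_dist_to_centers(X, filled[idx])[:, 0]
    for _ in range(1, k):
        total = d2.sum()
        if total <= 0:
            idx.append(int(rng.integers(n)))
            continue
        cands = rng.choice(n, size=n_cand, p=d2 / total)
        best_c, best_pot, best_d2 = None, np.inf, None
        for c in cands:
            cand_d2 = np.minimum(d2, _sq_dist_to_centers(X, filled[[c]])[:, 0])
            pot = cand_d2.sum()
            if pot < best_pot:
                best_c, best_pot, best_d2 = int(c), pot, cand_d2
        idx.append(best_c)
        d2 = best_d2
    return np.array(idx)


def _lloyd(X: np.ndarray, init_idx: np.ndarray, max_iter: int) -> tuple:
    k = len(init_idx)
    gm = _global_mean(X)
    centers = np.array([
        np.where(np.isnan(X[i]), gm, X[i]) for i in init_idx
    ])
    assign = np.full(len(X), -1)
    repairs = 0
    for it in range(1, max_iter + 1):
        d2 = _sq_dist_to_centers(X, centers)
        new_assign = d2.argmin(axis=1)
        # empty-cluster repair: reseed with the farthest trajectory
        for c in range(k):
            if not (new_assign == c).any():
                far = d2[np.arange(len(X)), new_assign].argmax()
                new_assign[far] = c
                repairs += 1
        if (new_assign == assign).all():
            break
        assign = new_assign
        centers = _update_centers(X, assign, k, gm)
    d2 = _sq_dist_to_centers(X, centers)
    W = float(d2[np.arange(len(X)), assign].sum())
    return assign, centers, W, it, repairs


def kmeans_long(
    X: np.ndarray,
    k: int,
    n_starts: int = 20,
    max_iter: int = 200,
    seed: int = 0,
) -> ClusterSolution:
    """Best-of-``n_starts`` Lloyd K-means under the missing-aware metric.

    Starts are seeded from random distinct trajectories; for ``k = 2`` on
    small inputs every distinct seed pair is tried as well, which makes the
    small-sample solution effectively exhaustive.  Deterministic for fixed
    seed.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if k > n:
        raise TrajectoryError(f"k={k} exceeds number of trajectories {n}")
    rng = np.random.default_rng(seed)
    starts = [_kpp_init(X, k, rng) for _ in range(n_starts)]
    if k == 2 and n <= 16:
        starts.extend(np.array(p) for p in combinations(range(n), 2))
    best = None
    for s_idx, init in enumerate(starts):
        assign, centers, W, iters, repairs = _lloyd(X, np.asarray(init), max_iter)
        if best is None or W < best[2] - 1e-15:
            best = (assign, centers, W, iters, repairs, s_idx)
    assign, centers, W, iters, repairs, s_idx = best
    return ClusterSolution(
        k=k, assignment=assign, centers=centers, inertia=W,
        iterations=iters, best_start=s_idx, repairs=repairs,
    )


def ch_criterion(X: np.ndarray, solution: ClusterSolution) -> float:
    """Calinski-Harabasz-type criterion under the missing-aware distance.

    ``C = [B/(k-1)] / [W/(n-k)]`` with ``B`` the size-weighted squared
    distance of centers to the overall mean trajectory and ``W`` the
    within-cluster sum.  Returns ``+inf`` (flagging the solution) when
    ``W = 0``.
    """
    X = np.asarray(X, dtype=float)
    n, k = len(X), solution.k
    if k < 2 or n <= k:
        raise TrajectoryError("criterion requires 2 <= k < n")
    gm = _global_mean(X)
    d2 = _sq_dist_to_centers(X, solution.centers)
    W = float(d2[np.arange(n), solution.assignment].sum())
    sizes = np.bincount(solution.assignment, minlength=k)
    B = float(
        (sizes * ((solution.centers - gm) ** 2).sum(axis=1)).sum()
    )
    if W <= 1e-18 * max(1.0, B):
        solution.criterion_flag = "zero-within-dispersion"
        return float("inf")
    return (B / (k - 1)) / (W / (n - k))


def select_k(
    X: np.ndarray,
    k_range=range(2, 9),
    n_starts: int = 20,
    max_iter: int = 200,
    seed: int = 0,
) -> tuple[ClusterSolution, pd.DataFrame]:
    """Fit K-means for each k and return the criterion-maximizing solution
    plus the full per-k criterion table."""
    rows = []
    best_sol = None
    for i, k in enumerate(k_range):
        sol = kmeans_long(X, k, n_starts=n_starts, max_iter=max_iter, seed=seed + i)
        sol.criterion = ch_criterion(X, sol)
        rows.append((k, sol.criterion, sol.inertia, sol.iterations))
        if best_sol is None or sol.criterion > best_sol.criterion:
            best_sol = sol
    table = pd.DataFrame(rows, columns=["k", "criterion", "inertia", "iterations"])
    return best_sol, table


def posterior_probs(X: np.ndarray, solution: ClusterSolution) -> np.ndarray:
    """Soft membership: Gaussian kernel on the missing-aware distance with
    bandwidth from the pooled within-cluster variance W/(n-k).  Rows sum
    to 1; the reported fit summary is the mean assigned-cluster posterior."""
    X = np.asarray(X, dtype=float)
    n, k = len(X), solution.k
    sigma2 = solution.inertia / max(n - k, 1)
    d2 = _sq_dist_to_centers(X, solution.centers)
    if sigma2 <= 0:
        post = np.zeros((n, k))
        post[np.arange(n), d2.argmin(axis=1)] = 1.0
    else:
        logp = -d2 / (2.0 * sigma2)
        logp -= logp.max(axis=1, keepdims=True)
        post = np.exp(logp)
        post /= post.sum(axis=1, keepdims=True)
    solution.posterior = post
    return post


def mean_assigned_posterior(solution: ClusterSolution) -> np.ndarray:
    """Average posterior probability of the assigned cluster, per cluster."""
    if solution.posterior is None:
        raise TrajectoryError("call posterior_probs first")
    p_assigned = solution.posterior[
        np.arange(len(solution.assignment)), solution.assignment
    ]
    return np.array([
        p_assigned[solution.assignment == c].mean()
        if (solution.assignment == c).any() else np.nan
        for c in range(solution.k)
    ])


@dataclass(frozen=True)
class LabelRules:
    """Explicit trajectory-shape labelling rule.

    robust:       peak rise above baseline below ``delta_rise``;
    resilient:    decline from peak recovers at least ``rho`` of the rise;
    nonresilient: otherwise.  Level tags cut the baseline at
    ``level_thresholds`` (low / medium / high).
    """

    delta_rise: float = 0.02
    rho: float = 0.5
    level_thresholds: tuple = (0.05, 0.15)


def label_clusters(
    solution: ClusterSolution, rules: LabelRules | None = None
) -> dict[int, dict]:
    """Label each cluster center robust / resilient / nonresilient with a
    low/medium/high baseline level tag."""
    rules = rules or LabelRules()
    labels = {}
    for c in range(solution.k):
        center = solution.centers[c]
        b, p, e = center[0], float(center.max()), center[-1]
        rise = p - b
        if rise < rules.delta_rise:
            cat = "robust"
        elif (p - e) >= rules.rho * rise:
            cat = "resilient"
        else:
            cat = "nonresilient"
        lo, hi = rules.level_thresholds
        level = "low" if b < lo else ("medium" if b < hi else "high")
        labels[c] = {"category": cat, "level": level, "baseline": float(b),
                     "peak": p, "end": float(e)}
    solution.labels = labels
    return labels
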