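from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from frailtraj.trajectory_clustering import (
    ClusterSolution,
    LabelRules,
    TrajectoryError,
    _global_mean,
    _sq_dist_to_centers,
    _update_centers,
    build_trajectories,
    ch_criterion,
    kmeans_long,
    label_clusters,
    mean_assigned_posterior,
    posterior_probs,
    select_k,
    traj_distance,
)


def series_frame(entries):
    """entries: list of (row_id, [scores by month, None for missing])."""
    rows = []
    for rid, scores in entries:
        for m, s in enumerate(scores):
            if s is not None:
                rows.append({"row_id": rid, "month": m, "score": s})
    return pd.DataFrame(rows)


class TestBuildTrajectories:
    def test_full_and_truncated_and_dropped(self):
        frame = series_frame([
            ("full", [0.05] * 13),
            ("three", [0.05, 0.06, 0.07] + [None] * 10),
            ("two", [0.05, 0.06] + [None] * 11),
        ])
        X, roster = build_trajectories(frame)
        assert list(roster["row_id"]) == ["full", "three"]
        assert roster.attrs["n_dropped"] == 1
        assert (~np.isnan(X[0])).sum() == 13
        assert (~np.isnan(X[1])).sum() == 3

    def test_non_suffix_missingness_rejected(self):
        frame = series_frame([
            ("bad", [0.05, None, 0.07] + [0.05] * 10),
        ])
        with pytest.raises(TrajectoryError, match="non-suffix"):
            build_trajectories(frame)


class TestDistance:
    def test_identical_zero(self):
        a = np.full(13, 0.3)
        assert traj_distance(a, a) == 0.0

    def test_uniform_offset_closed_form(self):
        a = np.full(13, 0.2)
        b = np.full(13, 0.3)
        assert traj_distance(a, b) == pytest.approx(0.1 * np.sqrt(13))

    def test_missing_rescaling(self):
        """Shared support of half the anchors doubles the squared term."""
        a = np.array([0.1] * 6 + [np.nan] * 7)
        b = np.full(13, 0.2)
        # d^2 = (13/6) * 6 * 0.01 = 13 * 0.01 * ... check formula directly
        assert traj_distance(a, b) ** 2 == pytest.approx((13 / 6) * 6 * 0.01)
        one_shared = np.array([0.1] + [np.nan] * 12)
        assert traj_distance(one_shared, b) ** 2 == pytest.approx(13 * 0.01)

    def test_disjoint_support_error(self):
        a = np.array([0.1] * 3 + [np.nan] * 10)
        c = np.array([np.nan] * 6 + [0.1] * 7)
        with pytest.raises(TrajectoryError, match="share no observed"):
            traj_distance(a, c)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = rng.random(13)
        b = rng.random(13)
        b[9:] = np.nan
        assert traj_distance(a, b) == pytest.approx(traj_distance(b, a))


def brute_force_two_partition(X):
    """Exhaustive minimum within-cluster sum over all 2-partitions, with
    centers re-optimized per partition (weighted anchor-wise means)."""
    n = len(X)
    gm = _global_mean(X)
    best = np.inf
    for r in range(1, n // 2 + 1):
        for left in combinations(range(n), r):
            assign = np.ones(n, dtype=int)
            assign[list(left)] = 0
            centers = _update_centers(X, assign, 2, gm)
            d2 = _sq_dist_to_centers(X, centers)
            W = d2[np.arange(n), assign].sum()
            best = min(best, W)
    return best


class TestKMeans:
    def test_two_well_separated_groups_recovered(self):
        rng = np.random.default_rng(5)
        lo = 0.05 + rng.normal(0, 0.005, (40, 13))
        hi = 0.60 + rng.normal(0, 0.005, (40, 13))
        X = np.vstack([lo, hi])
        sol = kmeans_long(X, 2, n_starts=5, seed=1)
        assign = sol.assignment
        assert len(set(assign[:40])) == 1 and len(set(assign[40:])) == 1
        assert assign[0] != assign[40]

    def test_identical_trajectories_zero_inertia(self):
        X = np.full((10, 13), 0.2)
        sol = kmeans_long(X, 2, n_starts=3, seed=0)
        assert sol.inertia == pytest.approx(0.0, abs=1e-18)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        X = rng.random((50, 13))
        s1 = kmeans_long(X, 3, n_starts=5, seed=4)
        s2 = kmeans_long(X, 3, n_starts=5, seed=4)
        assert np.array_equal(s1.assignment, s2.assignment)
        assert s1.inertia == s2.inertia

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(TrajectoryError):
            kmeans_long(np.random.default_rng(0).random((3, 13)), 5)

    @pytest.mark.parametrize("seed", range(8))
    def test_exhaustive_oracle_small_n(self, seed):
        """n = 6, k = 2: the returned within-cluster sum equals the
        exhaustive minimum over all 31 bipartitions."""
        rng = np.random.default_rng(seed)
        X = rng.random((6, 13)) * 0.5
        if seed % 2:
            X[0, 10:] = np.nan  # include a truncated trajectory
        sol = kmeans_long(X, 2, n_starts=50, seed=seed)
        assert sol.inertia <= brute_force_two_partition(X) + 1e-12

    def test_objective_monotone_over_iterations(self):
        """Running Lloyd from the final centers cannot improve the fit."""
        rng = np.random.default_rng(2)
        X = rng.random((80, 13))
        X[rng.random(80) < 0.3, 9:] = np.nan
        sol = kmeans_long(X, 4, n_starts=10, seed=3)
        d2 = _sq_dist_to_centers(X, sol.centers)
        reassigned = d2.argmin(axis=1)
        W2 = d2[np.arange(len(X)), reassigned].sum()
        assert W2 <= sol.inertia + 1e-12


class TestCHCriterion:
    def test_matches_hand_computation(self):
        X = np.array([
            [0.0] * 13, [0.1] * 13, [1.0] * 13, [0.9] * 13,
        ])
        assign = np.array([0, 0, 1, 1])
        centers = np.array([[0.05] * 13, [0.95] * 13])
        sol = ClusterSolution(k=2, assignment=assign, centers=centers,
                              inertia=np.nan, iterations=1, best_start=0)
        # hand computation: every distance is complete, factor 13/13 = 1
        W = 4 * 13 * 0.05 ** 2
        B = 2 * 13 * 0.45 ** 2 * 2
        expected = (B / 1) / (W / 2)
        assert ch_criterion(X, sol) == pytest.approx(expected, abs=1e-10)

    def test_scale_invariance(self):
        rng = np.random.default_rng(11)
        X = rng.random((30, 13))
        sol = kmeans_long(X, 3, n_starts=5, seed=0)
        c1 = ch_criterion(X, sol)
        X2 = X * 3.7
        sol2 = ClusterSolution(k=3, assignment=sol.assignment,
                               centers=sol.centers * 3.7, inertia=np.nan,
                               iterations=1, best_start=0)
        assert ch_criterion(X2, sol2) == pytest.approx(c1, rel=1e-10)

    def test_k_equals_n_minus_one_finite(self):
        rng = np.random.default_rng(3)
        X = rng.random((6, 13))
        sol = kmeans_long(X, 5, n_starts=20, seed=1)
        c = ch_criterion(X, sol)
        assert np.isfinite(c) and c > 0

    def test_zero_within_returns_inf(self):
        X = np.vstack([np.full((3, 13), 0.1), np.full((3, 13), 0.9)])
        sol = kmeans_long(X, 2, n_starts=3, seed=0)
        assert ch_criterion(X, sol) == np.inf
        assert sol.criterion_flag == "zero-within-dispersion"

    def test_matches_independent_recomputation(self):
        """Two-line independent formula evaluation on random instances."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            X = rng.random((25, 13))
            sol = kmeans_long(X, 3, n_starts=5, seed=int(rng.integers(100)))
            gm = _global_mean(X)
            W = sum(
                traj_distance(X[i], sol.centers[sol.assignment[i]]) ** 2
                for i in range(len(X))
            )
            sizes = np.bincount(sol.assignment, minlength=3)
            B = sum(
                sizes[c] * traj_distance(sol.centers[c], gm) ** 2
                for c in range(3)
            )
            expected = (B / 2) / (W / (len(X) - 3))
            assert ch_criterion(X, sol) == pytest.approx(expected, abs=1e-10)


class TestSelectK:
    def test_two_class_mixture_selects_two(self):
        rng = np.random.default_rng(23)
        hits = 0
        for s in range(10):
            lo = 0.05 + rng.normal(0, 0.01, (60, 13))
            hi = 0.40 + rng.normal(0, 0.01, (60, 13))
            X = np.vstack([lo, hi])
            sol, table = select_k(X, k_range=range(2, 6), n_starts=5, seed=s)
            hits += sol.k == 2
        assert hits >= 8

    def test_criterion_table_complete(self):
        rng = np.random.default_rng(1)
        X = rng.random((40, 13))
        sol, table = select_k(X, k_range=range(2, 5), n_starts=3, seed=0)
        assert list(table["k"]) == [2, 3, 4]
        assert sol.criterion == table["criterion"].max()


class TestPosterior:
    def test_equidistant_gives_half(self):
        X = np.vstack([
            np.full((1, 13), 0.5),        # exactly between the centers
            np.full((2, 13), 0.1),
            np.full((2, 13), 0.9),
        ])
        sol = ClusterSolution(
            k=2, assignment=np.array([0, 0, 0, 1, 1]),
            centers=np.vstack([np.full(13, 0.0), np.full(13, 1.0)]),
            inertia=1.0, iterations=1, best_start=0,
        )
        post = posterior_probs(X, sol)
        np.testing.assert_allclose(post[0], [0.5, 0.5], atol=1e-9)
        np.testing.assert_allclose(post.sum(axis=1), 1.0)

    def test_tight_clusters_confident(self):
        rng = np.random.default_rng(31)
        X = np.vstack([
            0.05 + rng.normal(0, 0.004, (50, 13)),
            0.50 + rng.normal(0, 0.004, (50, 13)),
        ])
        sol = kmeans_long(X, 2, n_starts=5, seed=2)
        posterior_probs(X, sol)
        assert mean_assigned_posterior(sol).min() >= 0.95


class TestLabels:
    def solution_with_centers(self, centers):
        centers = np.asarray(centers, dtype=float)
        return ClusterSolution(
            k=len(centers), assignment=np.arange(len(centers)),
            centers=centers, inertia=0.1, iterations=1, best_start=0,
        )

    def test_rule_examples(self):
        flat = [0.03] * 13
        rise_and_return = [0.03] + [0.07] * 4 + [0.03] * 8
        monotone_rise = list(np.linspace(0.03, 0.20, 13))
        sol = self.solution_with_centers([flat, rise_and_return, monotone_rise])
        labels = label_clusters(sol)
        assert labels[0]["category"] == "robust"
        assert labels[1]["category"] == "resilient"
        assert labels[2]["category"] == "nonresilient"

    def test_level_tags(self):
        sol = self.solution_with_centers([
            [0.03] * 13, [0.08] * 13, [0.30] * 13,
        ])
        labels = label_clusters(sol, LabelRules())
        assert [labels[c]["level"] for c in range(3)] == ["low", "medium", "high"]
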