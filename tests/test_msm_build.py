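"""Supervised MSM construction: clustering, counting, reversible estimation."""

import numpy as np
import pytest

import msmfret as mf
from msmfret.hmm_refine import _reversible_projection

from conftest import random_reversible_msm


def naive_regular_space(points, radius):
    centers = [points[0]]
    for p in points[1:]:
        if all(np.linalg.norm(p - c) > radius for c in centers):
            centers.append(p)
    return np.array(centers)


class TestClustering:
    def test_two_separated_points(self):
        cm = mf.regular_space_cluster(np.array([[0.0, 0.0], [1.0, 1.0]]), 0.5)
        assert cm.n_clusters == 2

    def test_all_points_within_radius_of_first(self, rng):
        pts = np.array([[0.5, 0.5]]) + rng.uniform(-0.05, 0.05, size=(30, 2))
        cm = mf.regular_space_cluster(pts, 0.2)
        assert cm.n_clusters == 1
        assert np.array_equal(cm.centers[0], pts[0])

    def test_one_dimensional_trace(self):
        pts = np.array([0.0, 0.05, 0.2, 0.25, 0.5])
        cm = mf.regular_space_cluster(pts, 0.1)
        assert cm.centers.ravel().tolist() == [0.0, 0.2, 0.5]

    def test_matches_sequential_oracle(self, rng):
        pts = rng.uniform(0.0, 1.0, size=(400, 2))
        cm = mf.regular_space_cluster(pts, 0.15)
        assert np.array_equal(cm.centers, naive_regular_space(pts, 0.15))

    def test_idempotent_on_own_centers(self, rng):
        pts = rng.uniform(0.0, 1.0, size=(300, 2))
        cm = mf.regular_space_cluster(pts, 0.2)
        again = mf.regular_space_cluster(cm.centers, 0.2)
        assert np.array_equal(cm.centers, again.centers)

    def test_centers_mutually_separated(self, rng):
        pts = rng.uniform(0.0, 1.0, size=(500, 2))
        cm = mf.regular_space_cluster(pts, 0.1)
        d = np.linalg.norm(cm.centers[:, None] - cm.centers[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() > 0.1

    def test_every_point_covered(self, rng):
        pts = rng.uniform(0.0, 1.0, size=(500, 2))
        cm = mf.regular_space_cluster(pts, 0.12)
        dmin = np.min(
            np.linalg.norm(pts[:, None] - cm.centers[None, :], axis=2), axis=1
        )
        assert dmin.max() <= 0.12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mf.regular_space_cluster(np.empty((0, 2)), 0.1)


class TestAssignment:
    def test_center_maps_to_itself(self):
        cm = mf.ClusterModel(centers=np.array([[0.0, 0.0], [1.0, 0.0]]), radius=0.3)
        assert mf.assign_states(np.array([[1.0, 0.0]]), cm)[0] == 1

    def test_tie_broken_to_lowest_index(self):
        cm = mf.ClusterModel(
            centers=np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 5.0]]), radius=0.5
        )
        # (1, 0) is equidistant from centers 0 and 1
        assert mf.assign_states(np.array([[1.0, 0.0]]), cm)[0] == 0

    def test_matches_brute_force_scan(self, rng):
        cm = mf.ClusterModel(centers=rng.uniform(0, 1, size=(12, 2)), radius=0.05)
        pts = rng.uniform(0, 1, size=(200, 2))
        labels = mf.assign_states(pts, cm)
        for p, lab in zip(pts, labels):
            dists = [np.linalg.norm(p - c) for c in cm.centers]
            assert lab == int(np.argmin(dists))


class TestCounting:
    def test_adjacent_pairs(self):
        d = mf.DiscreteTrajectory(np.array([0, 0, 1]), time_step=1.0)
        C = mf.count_transitions([d], lag=1.0, n_states=2).counts
        assert C[0, 0] == 1 and C[0, 1] == 1 and C.sum() == 2

    def test_sliding_window_at_lag_two(self):
        d = mf.DiscreteTrajectory(np.array([0, 1, 0, 1]), time_step=1.0)
        C = mf.count_transitions([d], lag=2.0, n_states=2).counts
        assert C[0, 0] == 1 and C[1, 1] == 1 and C.sum() == 2

    def test_matches_double_loop_oracle(self, rng):
        states = rng.integers(0, 4, size=120)
        d = mf.DiscreteTrajectory(states, time_step=2.0)
        L = 3
        C = mf.count_transitions([d], lag=2.0 * L, n_states=4).counts
        expected = np.zeros((4, 4), dtype=int)
        for t in range(len(states) - L):
            expected[states[t], states[t + L]] += 1
        assert np.array_equal(C, expected)

    def test_count_conservation(self, rng):
        dtrajs = [
            mf.DiscreteTrajectory(rng.integers(0, 3, size=n), time_step=1.0)
            for n in (50, 7, 3, 80)
        ]
        L = 5
        C = mf.count_transitions(dtrajs, lag=float(L), n_states=3).counts
        assert C.sum() == sum(max(len(d) - L, 0) for d in dtrajs)

    def test_short_trajectory_contributes_nothing(self, caplog):
        short = mf.DiscreteTrajectory(np.array([0, 1]), time_step=1.0)
        with caplog.at_level("WARNING"):
            C = mf.count_transitions([short], lag=5.0, n_states=2).counts
        assert C.sum() == 0
        assert any("skipped" in r.message for r in caplog.records)

    def test_non_integer_lag_rejected(self):
        d = mf.DiscreteTrajectory(np.array([0, 1, 0]), time_step=2.0)
        with pytest.raises(ValueError):
            mf.count_transitions([d], lag=3.0, n_states=2)


class TestConnectedSet:
    def test_fully_connected_identity(self):
        C = mf.CountMatrix(np.ones((4, 4), dtype=int), lag=1.0)
        keep, sub = mf.largest_connected_set(C)
        assert np.array_equal(keep, np.arange(4))
        assert np.array_equal(sub.counts, C.counts)

    def test_block_diagonal_keeps_larger_block(self):
        C = np.zeros((5, 5), dtype=int)
        C[:3, :3] = 1
        C[3:, 3:] = 1
        keep, sub = mf.largest_connected_set(mf.CountMatrix(C, lag=1.0))
        assert np.array_equal(keep, [0, 1, 2])
        assert sub.counts.shape == (3, 3)

    def test_matches_reachability_oracle(self, rng):
        n = 8
        C = (rng.random((n, n)) < 0.25).astype(int)
        if not C.any():
            C[0, 1] = 1
        # Floyd-Warshall style reachability on the positive-count graph
        reach = (C > 0) | np.eye(n, dtype=bool)
        for k in range(n):
            reach |= reach[:, k : k + 1] & reach[k : k + 1, :]
        mutual = reach & reach.T
        comps = {frozenset(np.nonzero(mutual[i])[0].tolist()) for i in range(n)}
        largest = max(comps, key=lambda c: (len(c), -min(c)))
        keep, _ = mf.largest_connected_set(mf.CountMatrix(C, lag=1.0))
        assert set(keep.tolist()) == set(largest)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            mf.largest_connected_set(mf.CountMatrix(np.zeros((3, 3), dtype=int), lag=1.0))


class TestReversibleEstimator:
    def test_symmetric_counts_give_row_normalized(self, rng):
        C = rng.integers(1, 30, size=(4, 4))
        C = C + C.T
        msm = mf.estimate_reversible_T(C.astype(float), lag=1.0)
        expected = C / C.sum(axis=1, keepdims=True)
        assert np.allclose(msm.transition_matrix, expected, atol=1e-10)

    def test_two_state_closed_form_and_grid(self):
        # Any 2-state chain is reversible, so the constrained MLE is the
        # plain row-normalized count matrix; a coarse grid search over the
        # 2-parameter simplex must not find a better likelihood.
        C = np.array([[13.0, 5.0], [3.0, 9.0]])
        msm = mf.estimate_reversible_T(C, lag=1.0)
        assert np.allclose(
            msm.transition_matrix, C / C.sum(axis=1, keepdims=True), atol=1e-10
        )
        ll_mle = float((C * np.log(msm.transition_matrix)).sum())
        grid = np.linspace(1e-3, 1 - 1e-3, 201)
        for a in grid:
            for b in grid:
                T = np.array([[1 - a, a], [b, 1 - b]])
                assert (C * np.log(T)).sum() <= ll_mle + 1e-9

    def test_estimator_contract(self, rng):
        for _ in range(10):
            C = rng.integers(1, 25, size=(5, 5)).astype(float)
            msm = mf.estimate_reversible_T(C, lag=1.0)
            assert np.max(np.abs(msm.transition_matrix.sum(axis=1) - 1.0)) < 1e-12
            assert msm.detailed_balance_residual() < 1e-10

    def test_likelihood_beats_reversible_projection_of_naive(self, rng):
        for _ in range(10):
            C = rng.integers(1, 25, size=(4, 4)).astype(float)
            mle = mf.estimate_reversible_T(C, lag=1.0)
            naive = C / C.sum(axis=1, keepdims=True)
            projected = _reversible_projection(naive, 1.0)
            ll_mle = (C * np.log(mle.transition_matrix)).sum()
            ll_proj = (C * np.log(projected.transition_matrix)).sum()
            assert ll_mle >= ll_proj - 1e-9

    def test_disconnected_counts_rejected(self):
        C = np.zeros((4, 4))
        C[:2, :2] = 5.0
        C[2:, 2:] = 5.0
        with pytest.raises(ValueError):
            mf.estimate_reversible_T(C, lag=1.0)


class TestImpliedTimescales:
    def test_two_state_analytic(self):
        # symmetric chain with hopping p: lambda_2 = 1 - 2p
        p = 0.1
        T = np.array([[1 - p, p], [p, 1 - p]])
        msm = mf.MarkovStateModel(T, lag=200.0, stationary=np.array([0.5, 0.5]))
        t = mf.implied_timescales(msm, 1)[0]
        assert t == pytest.approx(-200.0 / np.log(1 - 2 * p), rel=1e-12)

    def test_unit_eigenvalue_reported_infinite(self):
        msm = mf.MarkovStateModel(np.eye(2), lag=100.0, stationary=np.array([0.5, 0.5]))
        assert np.isinf(mf.implied_timescales(msm, 1)[0])

    def test_exponential_decay_reference(self):
        # eigenvalue e^-1 at tau=200 ns gives a 200 ns timescale
        lam = np.exp(-1.0)
        p = (1 - lam) / 2
        T = np.array([[1 - p, p], [p, 1 - p]])
        msm = mf.MarkovStateModel(T, lag=200.0, stationary=np.array([0.5, 0.5]))
        assert mf.implied_timescales(msm, 1)[0] == pytest.approx(200.0, rel=1e-12)

    def test_invariant_under_relabeling(self, rng):
        msm = random_reversible_msm(5, rng, lag=10.0)
        perm = rng.permutation(5)
        T2 = msm.transition_matrix[np.ix_(perm, perm)]
        msm2 = mf.MarkovStateModel(T2, lag=10.0, stationary=msm.stationary[perm])
        assert np.allclose(
            mf.implied_timescales(msm, 3),
            mf.implied_timescales(msm2, 3),
            rtol=1e-9,
            equal_nan=True,
        )

    def test_k_must_leave_trivial_eigenvalue(self, rng):
        msm = random_reversible_msm(3, rng)
        with pytest.raises(ValueError):
            mf.implied_timescales(msm, 3)


class TestPipelineAndIO:
    def test_feature_trajectory_validation(self):
        with pytest.raises(ValueError):
            mf.FeatureTrajectory(time_step=1.0, q=[0.5, 1.5], r=[10.0, 10.0])
        with pytest.raises(ValueError):
            mf.FeatureTrajectory(time_step=1.0, q=[0.5, 0.5], r=[10.0, -1.0])

    def test_expected_efficiency_matches_forster(self):
        traj = mf.FeatureTrajectory(
            time_step=1.0, q=np.array([0.1, 0.9]), r=np.array([56.0, 0.0])
        )
        eps = mf.expected_efficiency_trajectory(traj, r0=56.0, lam=1.0)
        assert eps == pytest.approx([0.5, 1.0])

    def test_roundtrip_files(self, tmp_path, benchmark3):
        traj = mf.generate_feature_trajectories(benchmark3, 1, 100, seed=3)[0]
        p = tmp_path / "traj.tsv"
        mf.write_feature_trajectory(traj, p)
        back = mf.read_feature_trajectory(p)
        assert back.time_step == pytest.approx(traj.time_step)
        assert np.allclose(back.q, traj.q) and np.allclose(back.r, traj.r)

        mpath = tmp_path / "msm.json"
        mf.save_msm(benchmark3.true_model, mpath)
        loaded = mf.load_msm(mpath)
        assert np.allclose(
            loaded.transition_matrix, benchmark3.true_model.transition_matrix
        )
        assert np.allclose(loaded.state_mean_r, benchmark3.true_model.state_mean_r)

    def test_build_msm_recovers_generator(self, benchmark3):
        trajs = mf.generate_feature_trajectories(benchmark3, 20, 5000, seed=9)
        msm, cluster = mf.build_msm(trajs, radius=0.15, lag=benchmark3.biased_model.lag)
        gen = benchmark3.biased_model
        assert msm.n_states == gen.n_states
        perm = np.argmin(
            np.linalg.norm(
                msm.state_centers[:, None, :] - gen.state_centers[None, :, :], axis=2
            ),
            axis=1,
        )
        inv = np.argsort(perm)
        T = msm.transition_matrix[np.ix_(inv, inv)]
        assert np.max(np.abs(T - gen.transition_matrix)) < 0.05
        assert np.allclose(msm.state_mean_r[inv], gen.state_mean_r, atol=1.0)
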