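"""Trajectory extraction, synchrony, GMM states and Markov estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncd import (
    ClusterTrajectory,
    PointPattern,
    Window,
    compare_groups,
    extract_trajectory,
    fit_state_model,
    synchrony,
    transition_matrix,
)
from ncd.errors import (
    DegenerateDataError,
    InsufficientDataError,
    ParameterError,
)
from ncd.synthetic import (
    gen_correlated_series,
    gen_dynamic_assembly,
    simulate_markov_chain,
)

ROI = Window.square(1500.0)


def _traj(da, db, ga=None, gb=None):
    n = len(da)
    nanarr = np.full(n, np.nan)
    return ClusterTrajectory(
        roi=ROI,
        times=np.arange(n) * 5.0,
        density_a=np.asarray(da, float),
        density_b=np.asarray(db, float),
        g_a=np.asarray(ga, float) if ga is not None else nanarr,
        g_b=np.asarray(gb, float) if gb is not None else nanarr,
        eom_short=nanarr,
    )


class TestExtractTrajectory:
    def test_series_length_matches_windows(self):
        da = gen_dynamic_assembly(n_windows=8, n_chains=1, seed=1)
        wins_a = [w[0] for w in da.chains[0]]
        wins_b = [w[1] for w in da.chains[0]]
        traj = extract_trajectory(wins_a, wins_b, ROI, seed=0, compute_eom=False)
        assert traj.n_windows == 8
        assert np.all(np.diff(traj.times) == 5.0)

    def test_empty_window_gives_zero_density_missing_g(self):
        win = Window.square(5000.0)
        empty = PointPattern(np.empty((0, 2)), win)
        full = PointPattern(np.array([[100.0, 100.0], [150.0, 160.0], [200.0, 100.0]]), win)
        traj = extract_trajectory([empty, full], [full, full], ROI, seed=0)
        assert traj.density_a[0] == 0.0
        assert np.isnan(traj.g_a[0]) and np.isnan(traj.eom_short[0])
        assert np.isfinite(traj.g_a[1])

    def test_assembly_raises_density(self):
        # absorbing clustered state: densities after absorption exceed the
        # dispersed starting level
        P = np.array([[0.5, 0.0, 0.5], [0.0, 0.5, 0.5], [0.0, 0.0, 1.0]])
        da = gen_dynamic_assembly(P, n_windows=12, n_chains=1, seed=4)
        states = da.states[0]
        first3 = np.argmax(states == 3)
        assert np.all(states[first3:] == 3)  # state 3 is absorbing
        wins_a = [w[0] for w in da.chains[0]]
        wins_b = [w[1] for w in da.chains[0]]
        traj = extract_trajectory(wins_a, wins_b, da.roi, seed=0, compute_eom=False)
        if first3 > 0:
            assert traj.density_a[states == 3].mean() > traj.density_a[states == 1].mean()

    def test_window_count_mismatch_rejected(self):
        win = Window.square(5000.0)
        p = PointPattern(np.array([[1.0, 1.0]]), win)
        with pytest.raises(ParameterError):
            extract_trajectory([p, p], [p], ROI)


class TestSynchrony:
    def test_identical_series_is_one(self):
        t = _traj([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert synchrony(t, "density") == pytest.approx(1.0)

    def test_negated_series_is_minus_one(self):
        t = _traj([1.0, 2.0, 3.0], [-1.0, -2.0, -3.0])
        assert synchrony(t, "density") == pytest.approx(-1.0)

    def test_constant_series_degenerate(self):
        t = _traj([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateDataError):
            synchrony(t, "density")

    def test_too_few_pairs_insufficient(self):
        t = _traj([1.0, 2.0], [2.0, 1.0])
        with pytest.raises(InsufficientDataError):
            synchrony(t, "density")

    def test_pairwise_complete_handling(self):
        ga = [1.0, np.nan, 3.0, 4.0, 5.0]
        gb = [1.0, 2.0, 3.0, np.nan, 5.0]
        t = _traj([0.0] * 5, [0.0] * 5, ga, gb)
        assert synchrony(t, "g") == pytest.approx(1.0)

    def test_programmed_correlation_recovered_unbiased(self):
        # 200 simulated trajectory pairs with true r = 0.8: the mean estimate
        # is within 0.05 of truth and truth lies inside the CI of the mean
        rng = np.random.default_rng(77)
        estimates = []
        for _ in range(200):
            xa, xb = gen_correlated_series(rho=0.8, n=48, seed=rng)
            estimates.append(synchrony(_traj(xa, xb), "density"))
        mean = np.mean(estimates)
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(mean - 0.8) < 0.05
        assert abs(mean - 0.8) < 3 * se + 0.01


class TestStateModel:
    def _blobs(self, rng, n=80):
        means = [(10.0, 1.0), (55.0, 1.2), (50.0, 7.0)]
        obs = np.vstack(
            [rng.normal(m, [3.0, 0.3], size=(n, 2)) for m in means]
        )
        labels = np.repeat([1, 2, 3], n)
        return obs, labels

    def test_well_separated_blobs_recovered(self, rng):
        obs, labels = self._blobs(rng)
        model = fit_state_model(obs, seed=0)
        agreement = np.mean(model.predict(obs) == labels)
        assert agreement >= 0.95

    def test_deterministic_under_seed(self, rng):
        obs, _ = self._blobs(rng)
        m1 = fit_state_model(obs, seed=3)
        m2 = fit_state_model(obs, seed=3)
        np.testing.assert_array_equal(m1.means, m2.means)
        np.testing.assert_array_equal(m1.weights, m2.weights)

    def test_label_convention_invariant_to_input_order(self, rng):
        obs, labels = self._blobs(rng)
        perm = rng.permutation(len(obs))
        m1 = fit_state_model(obs, seed=1)
        m2 = fit_state_model(obs[perm], seed=1)
        np.testing.assert_allclose(
            np.mean(m1.predict(obs) == labels), np.mean(m2.predict(obs) == labels)
        )
        # state 1 lowest density; state 3 highest g of the denser pair
        for m in (m1, m2):
            assert m.means[0, 0] == min(m.means[:, 0])
            assert m.means[2, 1] > m.means[1, 1]

    def test_too_few_observations_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_state_model(np.ones((10, 2)), seed=0)

    def test_degenerate_observations_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_state_model(np.ones((40, 2)), seed=0)


class TestTransitionMatrix:
    def test_constant_sequence(self):
        est = transition_matrix([[1, 1, 1, 1]])
        np.testing.assert_allclose(est.matrix[0], [1.0, 0.0, 0.0])
        assert set(est.uniform_rows) == {2, 3}
        np.testing.assert_allclose(est.matrix[1], [1 / 3] * 3)

    def test_alternating_sequence(self):
        est = transition_matrix([[1, 2, 1, 2, 1]])
        np.testing.assert_allclose(est.matrix[0], [0.0, 1.0, 0.0])
        np.testing.assert_allclose(est.matrix[1], [1.0, 0.0, 0.0])

    def test_invalid_labels_rejected(self):
        with pytest.raises(ParameterError):
            transition_matrix([[1, 4, 2]])

    def test_short_sequence_rejected(self):
        with pytest.raises(ParameterError):
            transition_matrix([[1]])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.integers(1, 3), min_size=2, max_size=30))
    def test_rows_sum_to_one(self, seq):
        est = transition_matrix([seq])
        np.testing.assert_allclose(est.matrix.sum(axis=1), 1.0)

    def test_recovery_at_study_scale(self):
        # 41 chains x 48 windows, pooled: entries recovered within 0.05 RMSE
        P = np.array([[0.90, 0.05, 0.05], [0.15, 0.70, 0.15], [0.10, 0.10, 0.80]])
        rng = np.random.default_rng(5)
        seqs = [simulate_markov_chain(P, 48, seed=rng) for _ in range(41)]
        est = transition_matrix(seqs)
        rmse = np.sqrt(np.mean((est.matrix - P) ** 2))
        assert rmse <= 0.05

    def test_most_persistent_state_dominates_stationary(self):
        P = np.array([[0.95, 0.03, 0.02], [0.30, 0.40, 0.30], [0.25, 0.15, 0.60]])
        rng = np.random.default_rng(9)
        seqs = [simulate_markov_chain(P, 48, seed=rng) for _ in range(41)]
        est = transition_matrix(seqs)
        assert np.argmax(est.stationary) == 0


class TestCompareGroups:
    def test_textbook_fixture(self):
        # pooled-variance hand calculation: t = -3.674 for {1,2,3} vs {4,5,6}
        res = compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.t == pytest.approx(-3.674, abs=1e-3)
        assert res.p < 0.05

    def test_identical_samples_give_zero_t(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_sem_reported(self):
        res = compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.sem_x == pytest.approx(1.0 / np.sqrt(3))

    def test_small_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_groups([1.0], [2.0, 3.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            compare_groups([2.0, 2.0], [2.0, 2.0])

    def test_power_at_two_sigma_shift(self):
        rng = np.random.default_rng(123)
        hits = 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(0.0, 1.0, 50)
            y = rng.normal(2.0, 1.0, 50)
            if compare_groups(x, y).p < 0.05:
                hits += 1
        assert hits / reps > 0.99
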