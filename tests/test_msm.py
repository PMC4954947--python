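"""Counting, connectivity, reversible MLE and implied timescales."""

import numpy as np
import pytest

from _oracles import reversible_mle_optimizer, scc_networkx
from msmbind.cluster import DiscreteTrajectory
from msmbind.msm import (
    CountModel,
    count_transitions,
    estimate_reversible,
    implied_timescales,
    lag_scan,
    largest_connected_set,
    stationary_distribution,
)
from msmbind.synthetic import exact_transition_matrix


def _dt(states, dt=1.0):
    return DiscreteTrajectory(np.asarray(states), dt)


class TestCounting:
    def test_lag_one_enumeration(self):
        cm = count_transitions([_dt([0, 0, 1, 1])], lag=1.0)
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 1]])

    def test_lag_two_enumeration(self):
        cm = count_transitions([_dt([0, 1, 0, 1, 0])], lag=2.0)
        np.testing.assert_array_equal(cm.counts, [[2, 0], [0, 1]])

    def test_counts_add_over_trajectories(self):
        a, b = [0, 1, 1], [1, 0, 0]
        joint = count_transitions([_dt(a), _dt(b)], lag=1.0).counts
        sep = count_transitions([_dt(a)], lag=1.0).counts + count_transitions([_dt(b)], lag=1.0).counts
        np.testing.assert_array_equal(joint, sep)

    def test_no_counting_across_boundaries(self):
        # two trajectories ending/starting in different states must not
        # contribute a spurious transition between them
        cm = count_transitions([_dt([0, 0]), _dt([1, 1])], lag=1.0)
        assert cm.counts[0, 1] == 0 and cm.counts[1, 0] == 0

    def test_all_short_trajectories_rejected(self):
        with pytest.raises(ValueError, match="shorter than the lag"):
            count_transitions([_dt([0, 1])], lag=5.0)

    def test_non_multiple_lag_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            count_transitions([_dt([0, 1, 0], dt=0.4)], lag=1.0)


class TestConnectivity:
    def test_fully_connected(self):
        np.testing.assert_array_equal(largest_connected_set(np.array([[5, 1], [1, 5]])), [0, 1])

    def test_disconnected_tie_prefers_larger_counts(self):
        assert largest_connected_set(np.array([[5, 0], [0, 9]])).tolist() == [1]

    def test_disconnected_exact_tie_prefers_lowest_index(self):
        assert largest_connected_set(np.array([[5, 0], [0, 5]])).tolist() == [0]

    def test_matches_graph_library_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            C = (rng.random((8, 8)) < 0.2) * rng.integers(1, 10, (8, 8))
            got = largest_connected_set(C).tolist()
            comps = scc_networkx(C)
            max_size = max(len(c) for c in comps)
            candidates = [c for c in comps if len(c) == max_size]
            assert got in [sorted(c) for c in candidates]
            assert len(got) == max_size


class TestReversibleMLE:
    def test_symmetric_counts_row_normalize(self):
        C = np.array([[9.0, 1.0], [1.0, 9.0]])
        m = estimate_reversible(CountModel(C, 1.0, "sliding", np.array([0, 1])))
        np.testing.assert_allclose(m.T, [[0.9, 0.1], [0.1, 0.9]], atol=1e-12)
        np.testing.assert_allclose(m.pi, [0.5, 0.5], atol=1e-12)

    def test_matches_generic_optimizer(self):
        C = np.array([[8.0, 2.0], [1.0, 9.0]])
        m = estimate_reversible(CountModel(C, 1.0, "sliding", np.array([0, 1])))
        np.testing.assert_allclose(m.T, reversible_mle_optimizer(C), atol=1e-8)

    def test_detailed_balance_and_stationarity(self):
        rng = np.random.default_rng(11)
        C = rng.integers(1, 40, (5, 5)).astype(float)
        m = estimate_reversible(CountModel(C, 1.0, "sliding", np.arange(5)))
        flux = m.pi[:, None] * m.T
        assert np.max(np.abs(flux - flux.T)) < 1e-8
        np.testing.assert_allclose(m.pi @ m.T, m.pi, atol=1e-8)
        np.testing.assert_allclose(m.T.sum(axis=1), 1.0, atol=1e-10)

    def test_loglik_below_unconstrained_optimum(self):
        rng = np.random.default_rng(12)
        C = rng.integers(1, 40, (4, 4)).astype(float)
        m = estimate_reversible(CountModel(C, 1.0, "sliding", np.arange(4)))
        T_free = C / C.sum(axis=1, keepdims=True)
        ll_free = np.sum(C[T_free > 0] * np.log(T_free[T_free > 0]))
        assert m.loglik <= ll_free + 1e-9

    def test_recovers_known_reversible_chain(self):
        # simulate a reversible 3-state chain and re-estimate it
        T_true = np.array([[0.90, 0.08, 0.02], [0.16, 0.80, 0.04], [0.08, 0.08, 0.84]])
        pi = stationary_distribution(T_true)
        flux = pi[:, None] * T_true
        assert np.max(np.abs(flux - flux.T)) < 1e-10  # sanity: constructed reversible
        rng = np.random.default_rng(13)
        n_steps = 1_000_000
        cum = np.cumsum(T_true, axis=1)
        states = np.empty(n_steps, dtype=np.int64)
        s = 0
        u = rng.random(n_steps)
        for t in range(n_steps):
            s = np.searchsorted(cum[s], u[t])
            states[t] = s
        m = estimate_reversible(count_transitions([_dt(states)], lag=1.0))
        assert np.max(np.abs(m.T - T_true)) < 0.01

    def test_invariant_to_trajectory_order_and_relabeling(self):
        rng = np.random.default_rng(14)
        trajs = [rng.integers(0, 3, 200) for _ in range(4)]
        m1 = estimate_reversible(count_transitions([_dt(t) for t in trajs], lag=1.0))
        m2 = estimate_reversible(count_transitions([_dt(t) for t in trajs[::-1]], lag=1.0))
        np.testing.assert_allclose(m1.T, m2.T, atol=1e-12)
        perm = np.array([2, 0, 1])  # relabel i -> perm[i]
        m3 = estimate_reversible(count_transitions([_dt(perm[t]) for t in trajs], lag=1.0))
        inv = np.argsort(perm)
        np.testing.assert_allclose(m3.T[np.ix_(perm, perm)], m1.T, atol=1e-10)
        assert inv is not None


class TestStationary:
    def test_two_state_hand_solve(self):
        np.testing.assert_allclose(
            stationary_distribution(np.array([[0.9, 0.1], [0.2, 0.8]])), [2 / 3, 1 / 3], atol=1e-12
        )

    def test_doubly_stochastic_uniform(self):
        T = np.array([[0.5, 0.3, 0.2], [0.2, 0.5, 0.3], [0.3, 0.2, 0.5]])
        np.testing.assert_allclose(stationary_distribution(T), np.ones(3) / 3, atol=1e-12)

    def test_identity_rejected_as_reducible(self):
        with pytest.raises(ValueError, match="reducible"):
            stationary_distribution(np.eye(3))


class TestImpliedTimescales:
    def test_closed_form_values(self):
        T = np.array([[0.5 + 0.5 * np.exp(-1), 0.5 - 0.5 * np.exp(-1)],
                      [0.5 - 0.5 * np.exp(-1), 0.5 + 0.5 * np.exp(-1)]])
        spec = implied_timescales(T, lag=1.0)
        assert spec.timescales[1] == pytest.approx(1.0, rel=1e-10)

    def test_derived_log_ratio(self):
        T = np.array([[0.85, 0.15], [0.15, 0.85]])  # lambda2 = 0.7
        spec = implied_timescales(T, lag=2.0)
        assert spec.timescales[1] == pytest.approx(-2.0 / np.log(0.7), rel=1e-10)
        assert spec.timescales[1] == pytest.approx(5.607, abs=1e-3)

    def test_unit_eigenvalue_maps_to_infinity(self):
        spec = implied_timescales(np.eye(2) * (1 - 1e-15) + 1e-15 / 2, lag=1.0)
        assert np.isinf(spec.timescales[1])

    def test_nonpositive_eigenvalue_undefined(self):
        T = np.array([[0.1, 0.9], [0.9, 0.1]])  # lambda2 = -0.8
        spec = implied_timescales(T, lag=1.0)
        assert np.isnan(spec.timescales[1])


class TestLagScan:
    def test_markovian_data_flat_curve(self):
        # exact Markov chain at frame resolution: tau2 independent of lag
        T = np.array([[0.95, 0.05], [0.10, 0.90]])
        rng = np.random.default_rng(15)
        cum = np.cumsum(T, axis=1)
        trajs = []
        for _ in range(20):
            s = rng.integers(2)
            out = np.empty(3000, np.int64)
            u = rng.random(3000)
            for t in range(3000):
                s = np.searchsorted(cum[s], u[t])
                out[t] = s
            trajs.append(_dt(out))
        lags = [1.0, 2.0, 4.0, 8.0]
        table, suggested = lag_scan(trajs, lags, n_timescales=1)
        tau2 = table["tau_2_ns"].to_numpy()
        assert np.nanmax(np.abs(tau2 / tau2[0] - 1)) < 0.15
        assert suggested == 1.0

    def test_hidden_fast_process_needs_longer_lag(self):
        # 3-state chain whose two lumped states mix slowly and exit at very
        # different rates: tau2 rises with lag before plateauing near the
        # true slow timescale, so the suggested lag exceeds the frame spacing
        K = np.array([[-0.3, 0.3, 0.0], [0.3, -1.3, 1.0], [0.0, 0.1, -0.1]])
        T1 = exact_transition_matrix(K, 0.1)
        rng = np.random.default_rng(16)
        cum = np.cumsum(T1, axis=1)
        lump = np.array([0, 0, 1])
        trajs = []
        for _ in range(100):
            s = rng.integers(3)
            out = np.empty(4000, np.int64)
            u = rng.random(4000)
            for t in range(4000):
                s = np.searchsorted(cum[s], u[t])
                out[t] = s
            trajs.append(DiscreteTrajectory(lump[out], 0.1))
        lags = [0.1, 1.0, 2.0, 4.0, 8.0, 12.0]
        table, suggested = lag_scan(trajs, lags, n_timescales=1)
        tau2 = table["tau_2_ns"].to_numpy()
        assert tau2[1] > tau2[0] * 1.1  # lumping bias at the frame-resolution lag
        assert suggested is not None and suggested > 0.1

    def test_single_lag_rejected(self):
        with pytest.raises(ValueError, match="two lags"):
            lag_scan([_dt([0, 1, 0, 1])], [1.0])


class TestBinding5Timescale:
    def test_tau2_recovered_within_15_percent(self, binding5, binding5_large):
        dtrajs_true, _ = binding5_large
        lag = 2.0
        dts = [DiscreteTrajectory(d, binding5.frame_dt) for d in dtrajs_true]
        m = estimate_reversible(count_transitions(dts, lag))
        est = implied_timescales(m).timescales[1]
        lam2 = np.sort(np.linalg.eigvals(exact_transition_matrix(binding5.rate_matrix, lag)).real)[::-1][1]
        exact = -lag / np.log(lam2)
        assert abs(est / exact - 1) < 0.15
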