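"""Generators versus their own analytic oracles."""

import numpy as np
import pytest

from _oracles import mc_mfpt_ctmc
from msmbind.synthetic import (
    BrownianConfig,
    GroundTruthSystem,
    RateMatrix,
    StateEmbedding,
    brownian_binding_trajectories,
    embed_states,
    exact_mfpt,
    exact_stationary,
    exact_transition_matrix,
    preset,
    sample_ctmc_trajectories,
)

K_SYM = np.array([[-1.0, 1.0], [1.0, -1.0]])
K_ASYM = np.array([[-2.0, 2.0], [1.0, -1.0]])


class TestRateMatrix:
    def test_negative_offdiagonal_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            RateMatrix(np.array([[1.0, -1.0], [1.0, -1.0]]))

    def test_non_conservative_rejected(self):
        with pytest.raises(ValueError, match="sum to zero"):
            RateMatrix(np.array([[-1.0, 2.0], [1.0, -1.0]]))

    def test_absorbing_rows_detected(self):
        rm = RateMatrix(np.array([[-1.0, 1.0], [0.0, 0.0]]))
        assert rm.absorbing_states.tolist() == [1]


class TestExactOracles:
    @pytest.mark.parametrize(
        "K, expected",
        [
            (K_SYM, [0.5, 0.5]),
            (K_ASYM, [1 / 3, 2 / 3]),
        ],
    )
    def test_stationary_small_systems(self, K, expected):
        np.testing.assert_allclose(exact_stationary(RateMatrix(K)), expected, atol=1e-12)

    def test_stationary_cycle_uniform(self):
        K = np.array([[-1.0, 1.0, 0.0], [0.0, -1.0, 1.0], [1.0, 0.0, -1.0]])
        np.testing.assert_allclose(exact_stationary(RateMatrix(K)), np.ones(3) / 3, atol=1e-12)

    def test_stationary_reducible_rejected(self):
        K = np.array([[-1.0, 1.0, 0.0], [1.0, -1.0, 0.0], [0.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="reducible"):
            exact_stationary(RateMatrix(K))

    def test_transition_matrix_zero_lag_identity(self):
        np.testing.assert_allclose(exact_transition_matrix(K_ASYM, 0.0), np.eye(2), atol=1e-14)

    def test_transition_matrix_two_state_closed_form(self):
        T = exact_transition_matrix(K_SYM, 1.0)
        e = np.exp(-2.0)
        expected = np.array([[(1 + e) / 2, (1 - e) / 2], [(1 - e) / 2, (1 + e) / 2]])
        np.testing.assert_allclose(T, expected, atol=1e-12)

    def test_transition_matrix_rows_sum_to_one(self):
        for K in (K_SYM, K_ASYM, preset("binding5").rate_matrix.K):
            T = exact_transition_matrix(K, 3.7)
            np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)

    def test_transition_matrix_negative_lag_rejected(self):
        with pytest.raises(ValueError):
            exact_transition_matrix(K_SYM, -0.1)

    def test_mfpt_two_state_exponential_waiting(self):
        assert exact_mfpt(RateMatrix(K_ASYM), 0, 1) == pytest.approx(0.5)

    def test_mfpt_source_inside_target_is_zero(self):
        assert exact_mfpt(RateMatrix(K_ASYM), 1, [0, 1]) == 0.0

    def test_mfpt_three_state_chain_sums_dwell_times(self):
        # 1 -> 2 -> 3 with unit rates; MFPT = 1 + 1 = 2 ns
        K = np.array([[-1.0, 1.0, 0.0], [0.0, -1.0, 1.0], [0.0, 0.0, 0.0]])
        assert exact_mfpt(RateMatrix(K), 0, 2) == pytest.approx(2.0)

    @pytest.mark.parametrize("name", ["twostate", "binding5"])
    def test_mfpt_matches_gillespie_first_passage(self, name):
        system = preset(name)
        rng = np.random.default_rng(42)
        times = mc_mfpt_ctmc(system.rate_matrix.K, system.bulk_state, [system.bound_state], 10_000, rng)
        predicted = exact_mfpt(system.rate_matrix, system.bulk_state, system.bound_state)
        ci = 2.576 * times.std(ddof=1) / np.sqrt(times.size)
        assert abs(times.mean() - predicted) < ci


class TestCtmcSampling:
    def test_zero_rates_give_constant_sequence(self):
        rm = RateMatrix(np.zeros((2, 2)))
        system = GroundTruthSystem(rm, StateEmbedding(np.eye(2)), 0, 1, frame_dt=0.1)
        with pytest.warns(UserWarning, match="absorbing"):
            dtrajs = sample_ctmc_trajectories(system, 1, 50, seed=0, start_state=0)
        assert np.all(dtrajs[0] == 0)

    def test_symmetric_occupancy_half(self):
        system = GroundTruthSystem(RateMatrix(K_SYM), StateEmbedding(np.eye(2)), 0, 1, frame_dt=0.1)
        dtrajs = sample_ctmc_trajectories(system, 10, 100_000, seed=1)
        occ = np.mean(np.concatenate(dtrajs) == 0)
        # stationary start; 3 SE with integrated autocorrelation time
        lam = np.exp(-2 * 0.1)
        tau_int = 0.5 * (1 + lam) / (1 - lam)
        se = np.sqrt(0.25 * 2 * tau_int / 1_000_000)
        assert abs(occ - 0.5) < 3 * se

    def test_mean_dwell_time_matches_rate(self):
        # dwell in state 0 is exponential with mean 1/|K_00| = 0.5 ns
        system = GroundTruthSystem(
            RateMatrix(K_ASYM), StateEmbedding(np.eye(2)), 0, 1, frame_dt=0.01
        )
        dtrajs = sample_ctmc_trajectories(system, 5, 100_000, seed=2)
        dwells = []
        for d in dtrajs:
            changes = np.flatnonzero(np.diff(d) != 0)
            bounds = np.concatenate([[-1], changes, [len(d) - 1]])
            for a, b in zip(bounds[:-1], bounds[1:]):
                if d[a + 1] == 0 and a >= 0 and b < len(d) - 1:  # complete runs only
                    dwells.append((b - a) * 0.01)
        dwells = np.asarray(dwells)
        se = dwells.std(ddof=1) / np.sqrt(dwells.size)
        assert abs(dwells.mean() - 0.5) < 3 * se + 0.01  # + one-frame discretization bias

    def test_occupancies_converge_to_stationary(self, binding5):
        dtrajs = sample_ctmc_trajectories(binding5, 100, 2000, seed=3)
        occ = np.bincount(np.concatenate(dtrajs), minlength=5) / (100 * 2000)
        pi = exact_stationary(binding5.rate_matrix)
        # generous 3-SE-style bound with long correlation times
        assert np.max(np.abs(occ - pi)) < 0.05

    def test_empirical_transition_frequencies_match_exact(self, twostate):
        dtrajs = sample_ctmc_trajectories(twostate, 50, 5000, seed=4)
        lagf = 10
        T_exact = exact_transition_matrix(twostate.rate_matrix, lagf * twostate.frame_dt)
        C = np.zeros((2, 2))
        for d in dtrajs:
            np.add.at(C, (d[:-lagf], d[lagf:]), 1.0)
        T_emp = C / C.sum(axis=1, keepdims=True)
        n_trans = C.sum()
        assert np.max(np.abs(T_emp - T_exact)) <= 5.0 / np.sqrt(n_trans)

    def test_bit_reproducible_for_fixed_seed(self, binding5):
        a = sample_ctmc_trajectories(binding5, 5, 500, seed=9)
        b = sample_ctmc_trajectories(binding5, 5, 500, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_metadata_flags_absorption(self):
        rm = RateMatrix(np.array([[-1.0, 1.0], [0.0, 0.0]]))
        system = GroundTruthSystem(rm, StateEmbedding(np.eye(2)), 0, 1, frame_dt=0.1)
        with pytest.warns(UserWarning, match="absorbing"):
            _, meta = sample_ctmc_trajectories(system, 3, 200, seed=0, start_state=0, with_metadata=True)
        assert all(meta["absorbed"])


class TestEmbedding:
    def test_zero_noise_reproduces_centroids(self):
        emb = StateEmbedding(np.array([[1.0, 2.0], [3.0, 4.0]]), noise_sd=0.0)
        ft = embed_states(np.array([0, 1, 0]), emb, seed=0)
        np.testing.assert_array_equal(ft.frames, [[1, 2], [3, 4], [1, 2]])

    def test_noise_sd_calibrated(self):
        emb = StateEmbedding(np.zeros((1, 3)), noise_sd=1.0)
        ft = embed_states(np.zeros(100_000, dtype=int), emb, seed=5)
        sds = ft.frames.std(axis=0, ddof=1)
        assert np.all(sds > 0.97) and np.all(sds < 1.03)

    def test_symmetric_centroids_zero_mean(self):
        emb = StateEmbedding(np.array([[1.0, 0.0], [-1.0, 0.0]]), noise_sd=0.1)
        dtraj = np.tile([0, 1], 5000)
        ft = embed_states(dtraj, emb, seed=6)
        assert abs(ft.frames[:, 0].mean()) < 0.05

    def test_out_of_range_state_rejected(self):
        emb = StateEmbedding(np.eye(2))
        with pytest.raises(IndexError):
            embed_states(np.array([0, 2]), emb, seed=0)


class TestBrownian:
    def _free_config(self, **kw):
        defaults = dict(
            box_edge=200.0,
            diffusion_coeff=10.0,
            well_center=np.full(3, 100.0),
            well_depth=0.0,
            well_radius=20.0,
            dt=0.01,
            seed=12,
        )
        defaults.update(kw)
        return BrownianConfig(**defaults)

    def test_step_size_precondition(self):
        with pytest.raises(ValueError, match="RMS step"):
            self._free_config(dt=10.0)

    def test_free_diffusion_msd(self):
        cfg = self._free_config()
        trajs = brownian_binding_trajectories(cfg, 200, 60)
        lag = 10
        msd = np.mean(
            [np.sum((xyz[lag:] - xyz[:-lag]) ** 2, axis=1).mean() for xyz, _ in trajs]
        )
        expected = 6.0 * cfg.diffusion_coeff * lag * cfg.dt
        assert abs(msd / expected - 1.0) < 0.10

    def test_reflecting_walls_keep_positions_in_box(self):
        cfg = self._free_config(box_edge=20.0, well_center=np.full(3, 10.0), well_radius=5.0, dt=0.005)
        trajs = brownian_binding_trajectories(cfg, 20, 500)
        for xyz, _ in trajs:
            assert xyz.min() >= 0.0 and xyz.max() <= 20.0

    def test_attractive_well_increases_occupancy(self):
        base = dict(box_edge=40.0, diffusion_coeff=10.0, well_center=np.full(3, 20.0),
                    well_radius=8.0, dt=0.005, seed=13)
        frac = {}
        for depth in (0.0, 5.0):
            cfg = BrownianConfig(well_depth=depth, **base)
            trajs = brownian_binding_trajectories(cfg, 20, 2000)
            inside = [np.linalg.norm(xyz - cfg.well_center, axis=1) < cfg.well_radius for xyz, _ in trajs]
            frac[depth] = np.mean([m.mean() for m in inside])
        assert frac[5.0] > frac[0.0]

    def test_deeper_wells_bind_faster(self):
        # common random numbers across the depth ladder
        base = dict(box_edge=40.0, diffusion_coeff=10.0, well_center=np.full(3, 20.0),
                    well_radius=8.0, dt=0.005, seed=14)
        mean_entry = []
        for depth in (0.0, 3.0, 6.0):
            cfg = BrownianConfig(well_depth=depth, **base)
            trajs = brownian_binding_trajectories(cfg, 100, 1500, min_start_distance=12.0)
            entries = []
            for xyz, _ in trajs:
                r = np.linalg.norm(xyz - cfg.well_center, axis=1)
                hit = np.flatnonzero(r < 0.8 * cfg.well_radius)
                entries.append(hit[0] * cfg.dt if hit.size else 1500 * cfg.dt)
            mean_entry.append(np.mean(entries))
        assert mean_entry[0] > mean_entry[1] > mean_entry[2]

    def test_reproducible_for_fixed_seed(self):
        cfg = self._free_config()
        a = brownian_binding_trajectories(cfg, 3, 50)
        b = brownian_binding_trajectories(cfg, 3, 50)
        for (xa, _), (xb, _) in zip(a, b):
            np.testing.assert_array_equal(xa, xb)
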