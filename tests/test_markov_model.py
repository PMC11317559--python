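"""Transition-matrix estimation, spectrum, reversibilization, simulation."""

import numpy as np
import pytest
from scipy import sparse

import markovworm as mw
from markovworm import markov_model as mm


class TestEstimation:
    def test_alternating_labels_give_swap_matrix(self):
        labels = np.tile([0, 1], 500)
        model = mw.estimate_transition_matrix(labels, 1)
        np.testing.assert_allclose(model.P.toarray(), [[0, 1], [1, 0]])

    def test_fixture_recovery_within_sampling_error(self):
        fx = mw.generate_markov_fixture(
            "block", block_sizes=[2, 2], eps=0.05, n_steps=10**6, seed=0
        )
        model = mw.estimate_transition_matrix(fx.sequence, 1)
        P_hat = model.P.toarray()
        n_i = np.asarray(model.counts.sum(axis=1)).ravel()
        se = np.sqrt(fx.P * (1 - fx.P) / n_i[:, None])
        assert np.max(np.abs(P_hat - fx.P) - 3 * se) < 1e-9

    def test_rows_are_stochastic_and_counts_kept(self, worm_msm):
        part, model, _, _ = worm_msm
        row_sums = np.asarray(model.P.sum(axis=1)).ravel()
        occupied = np.asarray(model.counts.sum(axis=1)).ravel() > 0
        np.testing.assert_allclose(row_sums[occupied], 1.0, atol=1e-12)
        assert model.counts.sum() == len(part.labels) - model.tau_frames

    def test_sparsity_few_reachable_states_per_row(self, worm_msm):
        """At a short lag the dynamics only reaches a handful of states."""
        _, model, _, _ = worm_msm
        out_degree = np.diff(model.P.indptr)
        assert np.median(out_degree[out_degree > 0]) < 20

    def test_lag_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            mw.estimate_transition_matrix(np.array([0, 1, 0]), 5)

    def test_pooled_counts_do_not_cross_worm_boundaries(self):
        model = mw.estimate_transition_matrix([np.array([0, 0]), np.array([1, 1])], 1)
        C = model.counts.toarray()
        assert C[0, 1] == 0 and C[1, 0] == 0

    def test_hdf5_round_trip(self, worm_msm, tmp_path):
        _, model, _, _ = worm_msm
        model.to_hdf5(tmp_path / "m.h5")
        back = mw.TransitionModel.from_hdf5(tmp_path / "m.h5")
        assert (back.P != model.P).nnz == 0
        assert back.tau_frames == model.tau_frames


class TestStationary:
    def test_doubly_stochastic_gives_uniform(self):
        P = np.array([[0.5, 0.3, 0.2], [0.2, 0.5, 0.3], [0.3, 0.2, 0.5]])
        model = mw.TransitionModel.from_matrix(P)
        np.testing.assert_allclose(mw.stationary_distribution(model), 1 / 3, atol=1e-10)

    def test_two_state_balance_by_hand(self):
        model = mw.TransitionModel.from_matrix([[0.8, 0.2], [0.1, 0.9]])
        np.testing.assert_allclose(
            mw.stationary_distribution(model), [1 / 3, 2 / 3], atol=1e-12
        )

    def test_permutation_cycle_uniform(self):
        model = mw.TransitionModel.from_matrix(np.roll(np.eye(3), 1, axis=1))
        np.testing.assert_allclose(mw.stationary_distribution(model), 1 / 3, atol=1e-12)

    def test_reducible_chain_restricted_with_warning(self):
        # state 2 is transient: it feeds states {0, 1} and is never re-entered
        P = np.array([[0.5, 0.5, 0.0], [0.5, 0.5, 0.0], [0.4, 0.4, 0.2]])
        model = mw.TransitionModel.from_matrix(P)
        with pytest.warns(UserWarning, match="reducible"):
            pi = mw.stationary_distribution(model)
        assert pi[2] == 0.0
        np.testing.assert_allclose(pi[:2], 0.5, atol=1e-12)

    def test_pi_is_left_eigenvector(self, worm_msm):
        _, model, _, _ = worm_msm
        pi = mw.stationary_distribution(model)
        np.testing.assert_allclose(pi @ model.P.toarray(), pi, atol=1e-10)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(pi >= 0)


class TestSpectrum:
    def test_two_state_closed_form_relaxation(self):
        p = 0.1
        model = mw.TransitionModel.from_matrix([[1 - p, p], [p, 1 - p]], dt=1.0)
        spec = mw.spectrum(model, n_modes=2)
        assert spec.eigenvalues[0].real == pytest.approx(1.0, abs=1e-10)
        assert spec.relaxation_times_s[1] == pytest.approx(-1 / np.log(1 - 2 * p), abs=1e-10)

    def test_stationary_mode_has_no_relaxation_time(self, worm_msm):
        _, model, _, _ = worm_msm
        spec = mw.spectrum(model, n_modes=5)
        assert np.isnan(spec.relaxation_times_s[0])
        assert np.all(np.abs(spec.eigenvalues) <= 1 + 1e-10)

    def test_sparse_path_matches_dense_oracle(self, monkeypatch, rng):
        """Random stochastic matrices, N <= 8: the sparse eigensolver path
        must agree with dense brute-force eigendecomposition to 1e-8."""
        for n in (4, 6, 8):
            A = rng.random((n, n)) + 0.1
            P = A / A.sum(axis=1, keepdims=True)
            dense_vals = np.sort(np.real(np.linalg.eigvals(P)))[::-1]
            model = mw.TransitionModel.from_matrix(P)
            monkeypatch.setattr(mm, "DENSE_THRESHOLD", 0)
            spec_sparse = mw.spectrum(model, n_modes=n - 2)
            monkeypatch.setattr(mm, "DENSE_THRESHOLD", 600)
            np.testing.assert_allclose(
                np.real(spec_sparse.eigenvalues), dense_vals[: n - 2], atol=1e-8
            )

    def test_fixture_lambda2_recovered_within_3se(self):
        fx = mw.generate_markov_fixture("two_state", p01=0.2, p10=0.1, n_steps=10**6, seed=3)
        model = mw.estimate_transition_matrix(fx.sequence, 1)
        spec = mw.spectrum(model, n_modes=2)
        lam2_true = 1 - 0.2 - 0.1
        # SE of lambda2 = 1 - p01_hat - p10_hat from binomial row errors
        n0 = (fx.sequence[:-1] == 0).sum()
        n1 = (fx.sequence[:-1] == 1).sum()
        se = np.sqrt(0.2 * 0.8 / n0 + 0.1 * 0.9 / n1)
        assert abs(spec.eigenvalues[1].real - lam2_true) < 3 * se


class TestReversibilize:
    def test_already_reversible_unchanged(self):
        p = 0.3
        model = mw.TransitionModel.from_matrix([[1 - p, p], [p, 1 - p]])
        Pr, pi, _ = mw.reversibilize(model)
        np.testing.assert_allclose(Pr.toarray(), model.P.toarray(), atol=1e-12)

    def test_three_cycle_symmetrizes(self):
        C = np.roll(np.eye(3), 1, axis=1)
        model = mw.TransitionModel.from_matrix(C)
        Pr, _, _ = mw.reversibilize(model)
        np.testing.assert_allclose(Pr.toarray(), 0.5 * (C + C.T), atol=1e-12)

    def test_detailed_balance_elementwise(self, worm_msm):
        _, model, _, _ = worm_msm
        Pr, pi, _ = mw.reversibilize(model)
        F = sparse.diags(pi) @ Pr
        np.testing.assert_allclose(F.toarray(), F.toarray().T, atol=1e-10)
        np.testing.assert_allclose(np.asarray(Pr.sum(axis=1)).ravel(), 1.0, atol=1e-10)


class TestImpliedTimescales:
    def test_markov_fixture_is_flat(self):
        fx = mw.generate_markov_fixture(
            "two_state", p01=0.05, p10=0.02, n_steps=10**6, seed=5
        )
        table, diag = mw.implied_timescale_test(fx.sequence, range(1, 9), dt=1.0)
        t2 = table[table["mode"] == 2]["relaxation_time_s"].to_numpy()
        assert (t2.max() - t2.min()) / t2.mean() < 0.05
        assert diag["markovian"]

    def test_heavy_tailed_dwells_flagged_non_markovian(self):
        states = (mw.HiddenState("a", 40.0, -0.4), mw.HiddenState("b", 40.0, 0.4))
        cfg = mw.SyntheticWormConfig(
            duration_frames=10**6, hidden_states=states, seed=6,
            dwell_distribution="lomax", lomax_shape=1.3, noise_sd=0.0,
        )
        _, gt = mw.generate_posture_series(cfg)
        _, diag = mw.implied_timescale_test(
            gt.hidden_label_per_frame, [1, 2, 4, 8, 16, 32], dt=1.0
        )
        assert not diag["markovian"]
        assert diag["relative_growth_mode2"] > 0.2

    def test_overlong_lags_dropped_with_warning(self):
        labels = np.tile([0, 1], 8)
        with pytest.warns(UserWarning, match="dropped"):
            table, diag = mw.implied_timescale_test(labels, [1, 100])
        assert diag["dropped_lags"] == [100]


class TestSimulation:
    def test_deterministic_cycle_reproduced(self):
        model = mw.TransitionModel.from_matrix(np.roll(np.eye(3), 1, axis=1))
        seq = mw.simulate_symbols(model, 0, 9, seed=0)
        np.testing.assert_array_equal(seq, [0, 1, 2] * 3)

    def test_pair_frequencies_match_within_3se(self):
        P = np.array([[0.7, 0.3], [0.4, 0.6]])
        model = mw.TransitionModel.from_matrix(P)
        seq = mw.simulate_symbols(model, 0, 300_000, seed=1)
        est = mw.estimate_transition_matrix(seq, 1)
        n_i = np.asarray(est.counts.sum(axis=1)).ravel()
        se = np.sqrt(P * (1 - P) / n_i[:, None])
        assert np.all(np.abs(est.P.toarray() - P) < 3 * se)

    def test_seeded_simulation_reproducible(self, worm_msm):
        _, model, _, _ = worm_msm
        s0 = int(np.argmax(mw.stationary_distribution(model)))
        a = mw.simulate_symbols(model, s0, 500, seed=9)
        b = mw.simulate_symbols(model, s0, 500, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_dead_end_state_raises(self):
        P = sparse.csr_matrix(np.array([[0.0, 1.0], [0.0, 0.0]]))
        model = mw.TransitionModel(P=P, counts=P.copy(), tau_frames=1, dt=1.0)
        with pytest.raises(ValueError, match="state 1"):
            mw.simulate_symbols(model, 0, 10, seed=0)

    def test_master_equation_preserves_probability(self, worm_msm, rng):
        _, model, _, _ = worm_msm
        p = rng.random(model.n_states)
        p /= p.sum()
        p_next = p @ model.P.toarray()
        assert p_next.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(p_next >= 0)


class TestDecoding:
    def test_single_member_microstates_decode_deterministically(self):
        a = np.arange(40, dtype=float).reshape(8, 5)
        series = mw.PostureSeries(a=a, dt=1.0)
        space = mw.delay_embed(series, 2)
        part = mw.partition(space, space.n_windows, seed=0)  # one window per cell
        symbols = part.labels[::2]  # replay the original windows at the symbol step
        decoded = mw.decode_postures(symbols, part, tau_frames=2, seed=0)
        np.testing.assert_allclose(decoded.a, a[: decoded.n_frames], atol=1e-12)

    def test_decoded_marginals_match_source(self, worm_msm):
        part, model, series, _ = worm_msm
        from scipy.stats import ks_2samp

        sim = mw.simulate_symbols(model, int(part.labels[0]), 1_500, seed=2)
        decoded = mw.decode_postures(sim, part, model.tau_frames, seed=3)
        for col in range(2):
            d = ks_2samp(decoded.a[::7, col], series.a[::7, col]).statistic
            assert d < 0.08, f"mode {col} marginal KS distance {d}"

    def test_decoded_autocorrelation_matches_source(self, worm_msm):
        part, model, series, _ = worm_msm

        def acf(x, m):
            x = x - x.mean()
            c = np.correlate(x, x, "full")[len(x) - 1 : len(x) - 1 + m]
            return c / c[0]

        sims = [
            mw.decode_postures(
                mw.simulate_symbols(model, int(part.labels[0]), 1_000, seed=s),
                part, model.tau_frames, seed=s,
            )
            for s in range(4)
        ]
        m = 64
        src = acf(series.a[:, 0], m)
        sim_acfs = np.array([acf(d.a[:, 0], m) for d in sims])
        lo = sim_acfs.min(axis=0) - 0.1
        hi = sim_acfs.max(axis=0) + 0.1
        frac_inside = np.mean((src >= lo) & (src <= hi))
        assert frac_inside > 0.9

    def test_empty_microstate_rejected(self, worm_msm):
        part, model, _, _ = worm_msm
        missing = np.setdiff1d(np.arange(part.N + 1), part.labels)
        with pytest.raises((ValueError, IndexError)):
            mw.decode_postures(np.array([int(missing[0])]* 3), part, 8, seed=0)


def test_shuffled_floor_below_real_slow_mode(worm_msm):
    part, model, _, _ = worm_msm
    floor = mw.shuffled_eigenvalue_floor(part.labels, model.tau_frames, seed=0, n_shuffles=3)
    spec = mw.spectrum(model, n_modes=2)
    assert floor < np.real(spec.eigenvalues[1])
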