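"""Metastable splits, hierarchical subdivision, dwell statistics."""

import itertools

import numpy as np
import pytest

import markovworm as mw
from markovworm.coarse_graining import set_coherence

from conftest import best_label_match


def exhaustive_best_bipartition(Pr, pi):
    """Oracle: best min-coherence over ALL bipartitions (N <= 12)."""
    n = Pr.shape[0]
    Pr = Pr.toarray() if hasattr(Pr, "toarray") else np.asarray(Pr)
    best_score, best_set = -np.inf, None
    for bits in itertools.product([0, 1], repeat=n - 1):
        members = np.array([0] + [i + 1 for i, b in enumerate(bits) if b])
        others = np.setdiff1d(np.arange(n), members)
        if len(others) == 0:
            continue
        score = min(set_coherence(Pr, pi, members), set_coherence(Pr, pi, others))
        if score > best_score:
            best_score, best_set = score, members
    labels = np.ones(n, dtype=int)
    labels[best_set] = 0
    return labels, best_score


class TestMetastableSplit:
    def test_two_block_chain_recovered_exactly(self):
        fx = mw.generate_markov_fixture("block", block_sizes=[2, 2], eps=0.01)
        model = mw.TransitionModel.from_matrix(fx.P)
        Pr, pi, _ = mw.reversibilize(model)
        split = mw.metastable_split(Pr, pi)
        assert best_label_match(split.labels, np.array([0, 0, 1, 1])) == 1.0
        # oracle: exhaustive scan over all 2^4 bipartitions
        oracle_labels, oracle_score = exhaustive_best_bipartition(Pr, pi)
        assert split.score == pytest.approx(oracle_score, abs=1e-12)
        assert best_label_match(split.labels, oracle_labels) == 1.0

    def test_threshold_scan_matches_exhaustive_oracle_on_random_chains(self, rng):
        """For random reversible chains (N <= 8) the incremental threshold
        scan must find a split at least as coherent as any bipartition that
        respects the phi_2 order."""
        from markovworm.markov_model import reversible_eigenvectors

        for _ in range(5):
            n = int(rng.integers(4, 9))
            A = rng.random((n, n)) + 0.05
            A = A + A.T  # symmetric counts -> reversible chain
            P = A / A.sum(axis=1, keepdims=True)
            model = mw.TransitionModel.from_matrix(P)
            Pr, pi, _ = mw.reversibilize(model)
            split = mw.metastable_split(Pr, pi)
            _, phi = reversible_eigenvectors(Pr, pi, n_modes=2)
            order = np.lexsort((np.arange(n), phi[:, 1]))
            best = -np.inf
            for k in range(1, n):
                a, b = order[:k], order[k:]
                best = max(best, min(set_coherence(Pr, pi, a), set_coherence(Pr, pi, b)))
            assert split.score == pytest.approx(best, abs=1e-10)

    def test_uniform_chain_flagged_non_metastable(self):
        """i.i.d. uniform chain: the best min-coherence equals the uniform
        self-transition mass |S|/N = 1/2 and the split is flagged."""
        fx = mw.generate_markov_fixture("iid_uniform", n_states=4)
        model = mw.TransitionModel.from_matrix(fx.P)
        Pr, pi, _ = mw.reversibilize(model)
        split = mw.metastable_split(Pr, pi)
        assert split.score == pytest.approx(0.5, abs=1e-12)
        assert not split.metastable

    def test_constant_phi2_rejected(self):
        """A chain whose phi_2 carries no variation cannot be split."""
        Pr = np.full((3, 3), 1 / 3)
        pi = np.full(3, 1 / 3)
        with pytest.raises(ValueError, match="no metastable structure"):
            mw.metastable_split(Pr, pi, phi2=np.ones(3))

    def test_weakly_structured_chain_score_matches_closed_form(self):
        """Near-uniform chain with a slight two-block bias: the best
        min-coherence equals the block self-transition mass."""
        eps = 0.4
        fx = mw.generate_markov_fixture("block", block_sizes=[3, 3], eps=eps)
        model = mw.TransitionModel.from_matrix(fx.P)
        Pr, pi, _ = mw.reversibilize(model)
        split = mw.metastable_split(Pr, pi)
        assert split.score == pytest.approx(1 - eps, abs=1e-10)


class TestSubdivision:
    def test_two_targets_equal_single_split(self, worm_msm):
        _, model, _, _ = worm_msm
        hier = mw.build_hierarchy(model, 2)
        Pr, pi, kept = mw.reversibilize(model)
        split = mw.metastable_split(Pr, pi)
        lifted = np.zeros(model.n_states, dtype=int)
        lifted[kept] = split.labels
        assert best_label_match(hier.labels_at(2), lifted) == 1.0

    def test_hierarchical_four_blocks_recovered_in_coupling_order(self):
        fx = mw.generate_markov_fixture(
            "hierarchical", block_size=3, eps_inner=0.01, eps_outer=0.0005,
            n_steps=0, seed=0,
        )
        model = mw.TransitionModel.from_matrix(fx.P, counts_scale=10_000)
        hier = mw.build_hierarchy(model, 4)
        truth4 = np.repeat([0, 1, 2, 3], 3)
        assert best_label_match(hier.labels_at(4), truth4) == 1.0
        # first split must separate the superblocks (the slowest barrier)
        truth2 = np.repeat([0, 1], 6)
        assert best_label_match(hier.labels_at(2), truth2) == 1.0
        # oracle at the top level: exhaustive bipartition at N = 12
        Pr, pi, _ = mw.reversibilize(model)
        oracle_labels, _ = exhaustive_best_bipartition(Pr, pi)
        assert best_label_match(hier.labels_at(2), oracle_labels) == 1.0

    def test_levels_refine_and_conserve_measure(self, worm_msm):
        _, model, _, _ = worm_msm
        hier = mw.build_hierarchy(model, 4)
        for coarse, fine in zip(hier.levels[:-1], hier.levels[1:]):
            # refinement: fine labels determine coarse labels
            for f in np.unique(fine):
                assert len(np.unique(coarse[fine == f])) == 1
        for n_states in (1, 2, 3, 4):
            assert hier.measures_at(n_states).sum() == pytest.approx(1.0, abs=1e-10)

    def test_json_round_trip(self, worm_msm, tmp_path):
        _, model, _, _ = worm_msm
        hier = mw.build_hierarchy(model, 3)
        hier.to_json(tmp_path / "h.json")
        back = mw.StateHierarchy.from_json(tmp_path / "h.json")
        for a, b in zip(back.levels, hier.levels):
            np.testing.assert_array_equal(a, b)


class TestProjectLabels:
    def test_identity_hierarchy_constant(self):
        seq = np.array([3, 1, 4, 1, 5])
        out = mw.project_labels(np.zeros(6, dtype=int), seq)
        assert np.all(out == 0)

    def test_unseen_microstate_rejected(self):
        with pytest.raises(ValueError):
            mw.project_labels(np.zeros(3, dtype=int), np.array([0, 5]))

    def test_two_regime_worm_recovered(self):
        """Coarse labels of a forward/reversal worm track the hidden truth."""
        states = (
            mw.HiddenState("forward", 120.0, -0.45),
            mw.HiddenState("reversal", 40.0, +0.45),
        )
        cfg = mw.SyntheticWormConfig(
            duration_frames=12_000, hidden_states=states, seed=2, noise_sd=0.05
        )
        series, gt = mw.generate_posture_series(cfg)
        part = mw.partition(mw.delay_embed(series, 8), 40, seed=0)
        model = mw.estimate_transition_matrix(part.labels, 8, n_states=40, dt=series.dt)
        hier = mw.build_hierarchy(model, 2)
        seq = mw.project_labels(hier.labels_at(2), part.labels[::8])
        hidden = gt.hidden_label_per_frame[: len(part.labels) : 8][: len(seq)]
        assert best_label_match(seq, hidden) >= 0.9


class TestDwellStatistics:
    def test_alternating_labels_all_dwell_one_step(self):
        seq = np.tile([0, 1], 200)
        stats = mw.dwell_statistics(seq, dt_symbol=0.5, n_boot=0)
        assert np.all(stats.dwell_times_s == 0.5)

    def test_telegraph_recovers_both_timescales(self):
        """Two-state telegraph with dwell means (10, 2) s at dt = 1/16 s."""
        dt = 1 / 16
        tau1, tau2 = 10.0, 2.0
        fx = mw.generate_markov_fixture(
            "two_state", p01=dt / tau1, p10=dt / tau2, n_steps=2_500_000, seed=8
        )
        stats = mw.dwell_statistics(fx.sequence, dt, n_boot=0)
        assert len(stats.dwell_times_s) > 10_000
        assert abs(stats.tau1_s - tau1) < 3 * stats.tau1_se
        assert abs(stats.tau2_s - tau2) < 3 * stats.tau2_se
        lam2 = 1 - dt / tau1 - dt / tau2
        operator_time = -dt / np.log(lam2)
        assert stats.relaxation_time_s == pytest.approx(operator_time, rel=0.05)

    def test_few_dwells_refuse_fit(self):
        seq = np.array([0] * 30 + [1] * 30 + [0] * 30 + [1] * 30)
        with pytest.warns(UserWarning, match="refusing"):
            stats = mw.dwell_statistics(seq, 1.0)
        assert stats.tau1_s is None
        assert len(stats.dwell_times_s) > 0

    def test_ccdf_is_proper_survival_curve(self):
        fx = mw.generate_markov_fixture("two_state", p01=0.1, p10=0.2, n_steps=5_000, seed=1)
        stats = mw.dwell_statistics(fx.sequence, 1.0, n_boot=0)
        ccdf = stats.ccdf()
        assert ccdf["ccdf"].iloc[0] <= 1.0
        assert np.all(np.diff(ccdf["ccdf"]) <= 1e-12)


class TestKineticRates:
    def test_rates_match_hand_count(self):
        seq = np.array([0, 0, 0, 1, 1, 0, 0, 1])
        rates = mw.kinetic_rates(seq, dt_symbol=2.0)
        r01 = rates.set_index(["from", "to"]).loc[(0, 1), "rate_per_s"]
        assert r01 == pytest.approx(2 / (5 * 2.0))

    def test_telegraph_rates_recover_generator(self):
        dt = 1.0
        fx = mw.generate_markov_fixture("two_state", p01=0.02, p10=0.1, n_steps=400_000, seed=2)
        rates = mw.kinetic_rates(fx.sequence, dt).set_index(["from", "to"])
        assert rates.loc[(0, 1), "rate_per_s"] == pytest.approx(0.02, rel=0.05)
        assert rates.loc[(1, 0), "rate_per_s"] == pytest.approx(0.1, rel=0.05)
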