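"""Unit and property tests for the Bernoulli GLM-HMM."""

import numpy as np
import pytest

from puffstates import glmhmm, task_sim
from puffstates.glmhmm import (
    DecodeResult, GLMHMMParams, build_features, em_fit, emission_prob,
    forward_backward, per_state_trial_mask, relabel_states, select_num_states,
    state_occupancy,
)
from puffstates.task_sim import LEFT, RIGHT, TrialRecord

from conftest import enumerate_hmm_posteriors


def _trial(session, idx, dc, choice, correct, rewarded=None):
    return TrialRecord(
        mouse_id="m", session_id=session, trial_index=idx, level=7,
        cue_duration=2.0, delay=0.5, n_left=max(-dc, 0), n_right=max(dc, 0),
        delta_cues=dc, correct_side=correct, choice=choice,
        rewarded=(choice == correct) if rewarded is None else rewarded,
    )


class TestFeatures:
    def test_first_trial_has_no_history(self):
        X = build_features([_trial("s", 0, 3, RIGHT, RIGHT)])
        assert np.array_equal(X[0], [3, 0, 0, 0, 1])

    def test_history_after_rewarded_right(self):
        trials = [_trial("s", 0, 2, RIGHT, RIGHT), _trial("s", 1, -1, LEFT, LEFT)]
        X = build_features(trials)
        # trial 1 follows a rewarded right choice
        assert np.array_equal(X[1], [-1, 1, 0, 1, 1])

    def test_unrewarded_previous_trial_zeroes_prev_reward(self):
        trials = [_trial("s", 0, 2, LEFT, RIGHT), _trial("s", 1, 0, RIGHT, RIGHT)]
        X = build_features(trials)
        assert np.array_equal(X[1], [0, -1, 0, 0, 1])

    def test_five_trial_hand_computed_matrix(self):
        trials = [
            _trial("s", 0, 2, RIGHT, RIGHT),    # rewarded right
            _trial("s", 1, -3, LEFT, LEFT),     # rewarded left
            _trial("s", 2, 1, LEFT, RIGHT),     # error (chose left, right correct)
            _trial("s", 3, -2, RIGHT, LEFT),    # error
            _trial("s", 4, 0, RIGHT, RIGHT),    # rewarded right
        ]
        expected = np.array([
            [2, 0, 0, 0, 1],
            [-3, 1, 0, 1, 1],
            [1, -1, 1, -1, 1],
            [-2, -1, -1, 0, 1],
            [0, 1, -1, 0, 1],
        ], dtype=float)
        assert np.array_equal(build_features(trials), expected)

    def test_cross_session_input_rejected(self):
        trials = [_trial("a", 0, 1, RIGHT, RIGHT), _trial("b", 1, 1, RIGHT, RIGHT)]
        with pytest.raises(ValueError):
            build_features(trials)

    def test_unordered_input_rejected(self):
        trials = [_trial("s", 1, 1, RIGHT, RIGHT), _trial("s", 0, 1, RIGHT, RIGHT)]
        with pytest.raises(ValueError):
            build_features(trials)


class TestEmission:
    def test_zero_weights_give_half(self):
        x = np.array([3, 1, -1, 0, 1.0])
        assert emission_prob(np.zeros(5), x, RIGHT) == 0.5
        assert emission_prob(np.zeros(5), x, LEFT) == 0.5

    def test_bias_only_reduction(self):
        from scipy.special import expit
        w = np.array([0, 0, 0, 0, 0.7])
        x = np.array([0, 0, 0, 0, 1.0])
        assert emission_prob(w, x, RIGHT) == pytest.approx(expit(0.7), abs=1e-12)

    def test_closed_form_logistic(self):
        # w.x = 0.5 * 2 = 1 -> logistic(1)
        w = np.array([0.5, 0, 0, 0, 0])
        x = np.array([2, 0, 0, 0, 1.0])
        assert emission_prob(w, x, RIGHT) == pytest.approx(0.7310585786300049, abs=1e-12)
        assert emission_prob(w, x, LEFT) == pytest.approx(1 - 0.7310585786300049, abs=1e-12)


class TestForwardBackward:
    def test_single_state_gamma_is_one(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.integers(-3, 4, 20), np.zeros((20, 3)), np.ones(20)])
        y = rng.integers(0, 2, 20)
        w = np.array([[0.8, 0, 0, 0, -0.2]])
        params = GLMHMMParams(w, np.ones((1, 1)), np.ones(1))
        dec = forward_backward(params, X, y, [20])
        assert np.allclose(dec.gamma, 1.0)
        ll = sum(np.log(emission_prob(w[0], X[t], int(y[t]))) for t in range(20))
        assert dec.loglik == pytest.approx(ll, abs=1e-10)

    def test_identical_states_give_uniform_posterior(self):
        K = 3
        W = np.tile([0.5, 0.1, 0, 0, 0.2], (K, 1))
        params = GLMHMMParams(W, np.full((K, K), 1 / K), np.full(K, 1 / K))
        rng = np.random.default_rng(1)
        X = np.column_stack([rng.integers(-3, 4, 15), np.zeros((15, 3)), np.ones(15)])
        y = rng.integers(0, 2, 15)
        dec = forward_backward(params, X, y, [15])
        assert np.allclose(dec.gamma, 1 / K, atol=1e-12)

    def test_matches_path_enumeration(self):
        """Forward-backward equals brute-force path enumeration on random
        small instances, including multi-session chains."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            K = int(rng.integers(1, 4))
            lengths = [int(rng.integers(1, 4)) for _ in range(rng.integers(1, 3))]
            T = sum(lengths)
            W = rng.normal(0, 1, (K, 5))
            A = rng.dirichlet(np.ones(K), K)
            pi0 = rng.dirichlet(np.ones(K))
            params = GLMHMMParams(W, A, pi0)
            X = np.column_stack([rng.integers(-3, 4, T),
                                 rng.choice([-1, 0, 1], (T, 2)),
                                 rng.choice([-1, 0, 1], T), np.ones(T)])
            y = rng.integers(0, 2, T)
            dec = forward_backward(params, X, y, lengths)
            g_ref, ll_ref = enumerate_hmm_posteriors(params, X, y, lengths)
            assert np.allclose(dec.gamma, g_ref, atol=1e-10)
            assert dec.loglik == pytest.approx(ll_ref, abs=1e-10)

    def test_xi_marginals_consistent_with_gamma(self, true_params, small_dataset):
        _, X, y, lengths = small_dataset
        dec = forward_backward(true_params, X, y, lengths)
        bounds = np.cumsum([0] + lengths)
        for i in range(len(lengths)):
            s, e = bounds[i], bounds[i + 1]
            for t in range(s, e - 1):
                assert np.allclose(dec.xi[t].sum(axis=1), dec.gamma[t], atol=1e-8)
                assert np.allclose(dec.xi[t].sum(axis=0), dec.gamma[t + 1], atol=1e-8)

    def test_extreme_weights_never_nan(self):
        params = GLMHMMParams(np.array([[50.0, 0, 0, 0, 0], [-50.0, 0, 0, 0, 0]]),
                              np.array([[0.9, 0.1], [0.1, 0.9]]), np.array([0.5, 0.5]))
        X = np.column_stack([np.full(10, 5.0), np.zeros((10, 3)), np.ones(10)])
        y = np.zeros(10, dtype=int)   # impossible under state 0, unlikely overall
        dec = forward_backward(params, X, y, [10])
        assert np.isfinite(dec.loglik)
        assert np.all(np.isfinite(dec.gamma))


class TestEMFit:
    def test_single_state_weight_recovery(self):
        """EM with K=1 reduces to logistic regression: weights recovered
        within 0.1 at 5,000 trials."""
        rng = np.random.default_rng(3)
        w_true = np.array([0.8, 0.3, -0.2, 0.4, -0.1])
        T = 5000
        X = np.column_stack([rng.integers(-4, 5, T), rng.choice([-1, 0, 1], (T, 2)),
                             rng.choice([-1, 0, 1], T), np.ones(T)])
        from scipy.special import expit
        y = (rng.random(T) < expit(X @ w_true)).astype(int)
        res = em_fit(X, y, [T], K=1, n_restarts=1, rng=0)
        assert np.abs(res.params.W[0] - w_true).max() < 0.1

    def test_loglik_monotone_nondecreasing(self, small_dataset):
        _, X, y, lengths = small_dataset
        res = em_fit(X, y, lengths, K=2, n_restarts=2, max_iter=50, rng=4)
        diffs = np.diff(res.loglik_trace)
        assert diffs.min() > -1e-8 * max(1.0, abs(res.loglik_trace[0]))

    def test_no_decrease_from_generating_parameters(self, true_params, small_dataset):
        _, X, y, lengths = small_dataset
        res = em_fit(X, y, lengths, K=3, init=true_params, max_iter=3, tol=0, rng=0)
        assert res.loglik_trace[1] >= res.loglik_trace[0] - 1e-8

    def test_identifiable_quantities_recovered(self, true_params):
        """At 20,000 trials the fit recovers the statistically identifiable
        structure: delta-cues weights, the summed history weights (their
        difference is near-collinear in high-accuracy states), transition
        diagonals, and MAP state labels."""
        spec = task_sim.SessionSpec(n_sessions=80, trials_per_session=250)
        trials = task_sim.simulate_glmhmm_behavior(spec, true_params, rng=7)
        X, y, lengths = glmhmm.build_design(trials)
        res = em_fit(X, y, lengths, K=3, n_restarts=2, rng=7)
        dec = forward_backward(res.params, X, y, lengths)
        pc, dc, _ = relabel_states(res.params, dec)
        assert np.abs(np.diag(pc.A) - np.diag(true_params.A)).max() < 0.03
        # delta-cues column and bias are well identified
        assert np.abs(pc.W[:, 0] - true_params.W[:, 0]).max() < 0.2
        # prev_choice_1 + prev_reward is identified even where the split is not
        hist = pc.W[:, 1] + pc.W[:, 3]
        hist_true = true_params.W[:, 1] + true_params.W[:, 3]
        assert np.abs(hist - hist_true).max() < 0.15
        # confidently decoded trials (posterior > 0.8) match generator labels
        # at a rate consistent with the posterior's own calibration
        truth = np.array([t.latent_state for t in trials])
        confident = dc.gamma.max(axis=1) > 0.8
        agreement = np.mean(dc.map_states[confident] == truth[confident])
        mean_confidence = dc.gamma.max(axis=1)[confident].mean()
        assert confident.mean() > 0.5
        assert agreement > 0.9
        assert abs(agreement - mean_confidence) < 0.03


class TestModelSelection:
    def test_single_row_table(self, small_dataset):
        _, X, y, lengths = small_dataset
        tab = select_num_states(X, y, lengths, [1], n_folds=2, n_restarts=1, rng=0)
        assert len(tab) == 1 and tab["K"].iloc[0] == 1

    def test_one_state_generator_shows_no_k2_gain(self):
        """Held-out gain of K=2 over K=1 is < 0.01 nats/trial when the data
        come from a single GLM."""
        rng = np.random.default_rng(5)
        w = np.array([0.9, 0, 0, 0, 0.2])
        sessions, lengths = [], []
        X_parts, y_parts = [], []
        from scipy.special import expit
        for _ in range(8):
            T = 500
            X = np.column_stack([rng.integers(-4, 5, T), rng.choice([-1, 0, 1], (T, 2)),
                                 rng.choice([-1, 0, 1], T), np.ones(T)])
            y = (rng.random(T) < expit(X @ w)).astype(int)
            X_parts.append(X)
            y_parts.append(y)
            lengths.append(T)
        X, y = np.concatenate(X_parts), np.concatenate(y_parts)
        tab = select_num_states(X, y, lengths, [1, 2], n_folds=2,
                                n_restarts=1, max_iter=80, rng=0)
        ll = dict(zip(tab["K"], tab["heldout_loglik_per_trial"]))
        assert ll[2] - ll[1] < 0.01

    def test_elbow_at_three_states(self, true_params):
        """For well-separated 3-state data the held-out gain from 2->3
        states exceeds the gain from 3->4."""
        spec = task_sim.SessionSpec(n_sessions=24, trials_per_session=250)
        trials = task_sim.simulate_glmhmm_behavior(spec, true_params, rng=6)
        X, y, lengths = glmhmm.build_design(trials)
        tab = select_num_states(X, y, lengths, [2, 3, 4], n_folds=2,
                                n_restarts=2, max_iter=100, rng=1)
        ll = dict(zip(tab["K"], tab["heldout_loglik_per_trial"]))
        assert ll[3] - ll[2] > ll[4] - ll[3]


class TestRelabeling:
    def _canonical(self):
        W = np.array([[2.0, 0.1, 0.0, 0.1, 0.2],
                      [0.1, 1.5, 0.8, -0.5, 0.0],
                      [0.1, 0.0, 0.0, 0.0, 0.3]])
        A = np.array([[0.9, 0.05, 0.05], [0.1, 0.8, 0.1], [0.2, 0.2, 0.6]])
        return GLMHMMParams(W, A, np.array([0.5, 0.3, 0.2]))

    def test_canonical_params_fixed_point(self):
        p = self._canonical()
        q, _, perm = relabel_states(p)
        assert np.array_equal(perm, [0, 1, 2])
        assert np.array_equal(q.W, p.W)

    def test_relabeling_is_involution_on_swaps(self):
        p = self._canonical()
        swapped = p.permuted(np.array([1, 2, 0]))
        q, _, _ = relabel_states(swapped)
        assert np.allclose(q.W, p.W)
        assert np.allclose(q.A, p.A)
        assert np.allclose(q.pi0, p.pi0)

    def test_non_three_state_passthrough(self):
        p = GLMHMMParams(np.zeros((2, 5)), np.eye(2), np.array([0.5, 0.5]))
        _, _, perm = relabel_states(p)
        assert np.array_equal(perm, [0, 1])

    def test_decode_permuted_consistently(self, true_params, small_dataset):
        _, X, y, lengths = small_dataset
        dec = forward_backward(true_params, X, y, lengths)
        shuffled = true_params.permuted(np.array([2, 0, 1]))
        dec_s = forward_backward(shuffled, X, y, lengths)
        pc, dc, perm = relabel_states(shuffled, dec_s)
        assert np.allclose(pc.W, true_params.W)
        assert np.allclose(dc.gamma, dec.gamma, atol=1e-10)

    def test_occupancy_invariant_under_relabeling_roundtrip(self, true_params,
                                                            small_dataset):
        _, X, y, lengths = small_dataset
        dec = forward_backward(true_params, X, y, lengths)
        occ = state_occupancy(dec)
        shuffled = true_params.permuted(np.array([1, 2, 0]))
        dec_s = forward_backward(shuffled, X, y, lengths)
        _, dc, _ = relabel_states(shuffled, dec_s)
        assert np.allclose(state_occupancy(dc), occ, atol=1e-12)


class TestOccupancyAndMasks:
    def _decode(self, gamma):
        T = gamma.shape[0]
        return DecodeResult(gamma=gamma, xi=np.zeros((T - 1, gamma.shape[1],
                                                      gamma.shape[1])),
                            loglik=0.0, session_lengths=[T])

    def test_dominant_state_occupancy(self):
        gamma = np.tile([0.9, 0.05, 0.05], (10, 1))
        assert np.array_equal(state_occupancy(self._decode(gamma)), [1, 0, 0])

    def test_uniform_gamma_ties_to_lowest_index(self):
        gamma = np.full((6, 3), 1 / 3)
        assert np.array_equal(state_occupancy(self._decode(gamma)), [1, 0, 0])

    def test_occupancy_matches_counting_oracle(self):
        rng = np.random.default_rng(8)
        gamma = rng.dirichlet(np.ones(3), 1000)
        occ = state_occupancy(self._decode(gamma))
        counts = np.zeros(3)
        for row in gamma:
            counts[int(np.argmax(row))] += 1
        assert np.allclose(occ, counts / 1000)

    def test_mask_threshold_is_strict(self):
        gamma = np.array([[0.8, 0.1, 0.1], [0.81, 0.1, 0.09], [0.79, 0.2, 0.01]])
        mask = per_state_trial_mask(self._decode(gamma), 0, 0.8)
        assert mask.tolist() == [False, True, False]

    def test_mask_counts_match_brute_force(self):
        rng = np.random.default_rng(9)
        gamma = rng.dirichlet(np.ones(3), 500)
        dec = self._decode(gamma)
        for k in range(3):
            mask = per_state_trial_mask(dec, k, 0.8)
            assert mask.sum() == sum(1 for row in gamma if row[k] > 0.8)

    def test_bad_threshold_rejected(self):
        gamma = np.full((3, 3), 1 / 3)
        with pytest.raises(ValueError):
            per_state_trial_mask(self._decode(gamma), 0, 1.0)
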