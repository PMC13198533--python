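"""Shared fixtures and independent brute-force oracles."""

import itertools

import numpy as np
import pytest

from puffstates import ddm, glmhmm, pipeline, task_sim


@pytest.fixture(scope="session")
def true_params():
    """Canonical 3-state ground truth used by the simulator fixtures."""
    return pipeline.default_true_params()


@pytest.fixture(scope="session")
def small_dataset(true_params):
    """4 sessions x 150 trials of simulated latent-state behavior."""
    spec = task_sim.SessionSpec(n_sessions=4, trials_per_session=150)
    trials = task_sim.simulate_glmhmm_behavior(spec, true_params, rng=123)
    X, y, lengths = glmhmm.build_design(trials)
    return trials, X, y, lengths


def enumerate_hmm_posteriors(params, X, y, lengths):
    """Exact HMM posteriors by explicit summation over all state paths.

    Independent of the forward-backward implementation: enumerates K^T paths
    per session and accumulates unnormalized path probabilities.
    Tractable only for tiny T and K.
    """
    K = params.K
    T = X.shape[0]
    gamma = np.zeros((T, K))
    loglik = 0.0
    start = 0
    for L in lengths:
        probs = {}
        for path in itertools.product(range(K), repeat=L):
            p = params.pi0[path[0]]
            for t in range(1, L):
                p *= params.A[path[t - 1], path[t]]
            for t in range(L):
                p *= glmhmm.emission_prob(params.W[path[t]], X[start + t],
                                          int(y[start + t]))
            probs[path] = p
        Z = sum(probs.values())
        loglik += np.log(Z)
        for path, p in probs.items():
            for t in range(L):
                gamma[start + t, path[t]] += p / Z
        start += L
    return gamma, loglik


def random_pulse_trial(rng, T=None, max_pulses=8):
    T = float(rng.uniform(1.0, 3.0)) if T is None else T
    n = int(rng.integers(1, max_pulses + 1))
    pulses = [(float(rng.uniform(0, T)), int(rng.choice([-1, 1]))) for _ in range(n)]
    return ddm.PulseTrial(pulses, T=T)


def simulate_ddm_dataset(params, n_trials, rng):
    """Draw task-like stimuli and choices from the analytic DDM likelihood."""
    trials, choices = [], []
    for _ in range(n_trials):
        cue = float(rng.uniform(1.0, 3.8))
        correct = task_sim.RIGHT if rng.random() < 0.5 else task_sim.LEFT
        rl = 2.0 if correct == task_sim.LEFT else 0.5
        puffs, *_ = task_sim.generate_trial_stimulus(rl, 2.5 - rl, cue,
                                                     correct_side=correct, rng=rng)
        pt = ddm.PulseTrial(
            [(p.time, task_sim.side_sign(p.side)) for p in puffs if p.kind == "evidence"],
            T=cue)
        trials.append(pt)
        choices.append(1 if rng.random() < ddm.choice_prob_right(params, pt) else 0)
    return trials, np.array(choices)
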