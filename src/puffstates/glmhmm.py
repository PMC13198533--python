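"""Bernoulli GLM-HMM of trial-by-trial choice strategy.

On each trial the animal occupies one of K latent states; each state k has
its own logistic (Bernoulli GLM) mapping from trial covariates to the
probability of a rightward choice,

    P(right | state k, x) = logistic(w_k . x),

with covariates x = (delta_cues, prev_choice_1, prev_choice_2, prev_reward,
bias).  States evolve as a first-order Markov chain with a fixed transition
matrix A and initial distribution pi0, reinitialized at every session start.
Fitting is by expectation-maximization: scaled forward-backward recursions
for the E-step, closed-form updates of A and pi0 and ridge-penalized
weighted logistic regressions for the per-state weights in the M-step.

A canonical state ordering for K = 3 labels state 1 as the evidence-driven
("on-task") state with the largest |delta-cues| weight, state 2 as the
history-driven state with the largest previous-choice weights among the
remainder, and state 3 as the residual (disengaged) state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_expit

from .task_sim import RIGHT, TrialRecord, side_sign

FEATURE_NAMES = ("delta_cues", "prev_choice_1", "prev_choice_2", "prev_reward", "bias")
N_FEATURES = len(FEATURE_NAMES)


@dataclass
class GLMHMMParams:
    """Model parameters: per-state GLM weights (log-odds per feature unit),
    state-transition matrix and initial state distribution."""

    W: np.ndarray          # (K, 5)
    A: np.ndarray          # (K, K), rows sum to 1
    pi0: np.ndarray        # (K,)

    def __post_init__(self):
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.pi0 = np.asarray(self.pi0, dtype=float).ravel()

    @property
    def K(self) -> int:
        return self.W.shape[0]

    def validate(self) -> None:
        K = self.K
        if K < 1 or self.W.shape != (K, N_FEATURES):
            raise ValueError(f"W must be (K, {N_FEATURES})")
        if self.A.shape != (K, K):
            raise ValueError("A must be K x K")
        if np.any(self.A < 0) or np.any(np.abs(self.A.sum(axis=1) - 1) > 1e-10):
            raise ValueError("rows of A must be nonnegative and sum to 1")
        if np.any(self.pi0 < 0) or abs(self.pi0.sum() - 1) > 1e-10:
            raise ValueError("pi0 must be a probability vector")

    def permuted(self, perm: np.ndarray) -> "GLMHMMParams":
        perm = np.asarray(perm)
        return GLMHMMParams(self.W[perm], self.A[np.ix_(perm, perm)], self.pi0[perm])

    def to_dict(self) -> dict:
        return {
            "W": self.W.tolist(), "A": self.A.tolist(), "pi0": self.pi0.tolist(),
            "feature_names": list(FEATURE_NAMES),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GLMHMMParams":
        return cls(np.array(d["W"]), np.array(d["A"]), np.array(d["pi0"]))


@dataclass
class DecodeResult:
    """Posterior decode: gamma[t, k] = P(state k | all choices), xi the
    within-session pairwise posteriors, and the total log-likelihood."""

    gamma: np.ndarray              # (T, K)
    xi: np.ndarray                 # (T-1, K, K); rows at session ends are 0
    loglik: float
    session_lengths: list[int]

    @property
    def map_states(self) -> np.ndarray:
        return np.argmax(self.gamma, axis=1)


def features_for_trial(delta_cues: int, prev: list[TrialRecord]) -> np.ndarray:
    """Feature vector for the trial following the (possibly empty) list of
    earlier trials in the same session."""
    x = np.zeros(N_FEATURES)
    x[0] = delta_cues
    if len(prev) >= 1:
        x[1] = side_sign(prev[-1].choice)
        if prev[-1].rewarded:
            x[3] = side_sign(prev[-1].correct_side)
    if len(prev) >= 2:
        x[2] = side_sign(prev[-2].choice)
    x[4] = 1.0
    return x


def build_features(trials: list[TrialRecord]) -> np.ndarray:
    """T x 5 design matrix for one session's trials, ordered by trial_index.

    History terms (previous two choices, previous reward side) are zero where
    the history does not exist at the session boundary.
    """
    if not trials:
        return np.zeros((0, N_FEATURES))
    sessions = {t.session_id for t in trials}
    if len(sessions) != 1:
        raise ValueError(f"build_features expects one session, got {sorted(sessions)}")
    idx = [t.trial_index for t in trials]
    if idx != sorted(idx) or len(set(idx)) != len(idx):
        raise ValueError("trials must be strictly ordered by trial_index")
    return np.stack([features_for_trial(t.delta_cues, trials[:i])
                     for i, t in enumerate(trials)])


def build_design(trials: list[TrialRecord]) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Stack features, signed choices in {0,1} (right=1), and session lengths
    across a multi-session trial list (sessions kept in encounter order)."""
    X_parts, y_parts, lengths = [], [], []
    by_session: dict[str, list[TrialRecord]] = {}
    order: list[str] = []
    for t in trials:
        key = f"{t.mouse_id}|{t.session_id}"
        if key not in by_session:
            by_session[key] = []
            order.append(key)
        by_session[key].append(t)
    for key in order:
        sess = sorted(by_session[key], key=lambda t: t.trial_index)
        X_parts.append(build_features(sess))
        y_parts.append(np.array([1 if t.choice == RIGHT else 0 for t in sess]))
        lengths.append(len(sess))
    return np.concatenate(X_parts), np.concatenate(y_parts), lengths


def emission_prob(w: np.ndarray, x: np.ndarray, y: str | int) -> float:
    """Bernoulli GLM emission: P(y | w, x) with P(right) = logistic(w.x)."""
    p_right = float(expit(np.dot(w, x)))
    right = (y == RIGHT) if isinstance(y, str) else bool(y)
    return p_right if right else 1.0 - p_right


def _emission_matrix(params: GLMHMMParams, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """B[t, k] = P(y_t | state k), computed in a numerically safe way."""
    z = X @ params.W.T                      # (T, K) log-odds of right
    sgn = np.where(y[:, None] == 1, 1.0, -1.0)
    return np.exp(log_expit(sgn * z))


def _fb_session(pi0, A, B, gamma, xi, start, L):
    """Scaled alpha/beta recursion for one session; fills gamma/xi slices in
    place and returns the session log-marginal."""
    K = pi0.shape[0]
    alpha = np.zeros((L, K))
    c = np.zeros(L)
    for k in range(K):
        alpha[0, k] = pi0[k] * B[start, k]
    c[0] = max(alpha[0].sum(), 1e-300)
    alpha[0] /= c[0]
    for t in range(1, L):
        for j in range(K):
            s = 0.0
            for i in range(K):
                s += alpha[t - 1, i] * A[i, j]
            alpha[t, j] = s * B[start + t, j]
        c[t] = max(alpha[t].sum(), 1e-300)
        alpha[t] /= c[t]
    beta = np.zeros((L, K))
    beta[L - 1] = 1.0
    for t in range(L - 2, -1, -1):
        for i in range(K):
            s = 0.0
            for j in range(K):
                s += A[i, j] * B[start + t + 1, j] * beta[t + 1, j]
            beta[t, i] = s / c[t + 1]
    for t in range(L):
        g = alpha[t] * beta[t]
        tot = max(g.sum(), 1e-300)
        gamma[start + t] = g / tot
    for t in range(L - 1):
        tot = 0.0
        for i in range(K):
            for j in range(K):
                m = alpha[t, i] * A[i, j] * B[start + t + 1, j] * beta[t + 1, j] / c[t + 1]
                xi[start + t, i, j] = m
                tot += m
        tot = max(tot, 1e-300)
        for i in range(K):
            for j in range(K):
                xi[start + t, i, j] /= tot
    return float(np.log(c).sum())


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _fb_session = njit(cache=False)(_fb_session)
except Exception:  # numba unavailable: pure-numpy fallback is identical
    pass


def forward_backward(
    params: GLMHMMParams,
    X: np.ndarray,
    y: np.ndarray,
    session_lengths: list[int] | None = None,
) -> DecodeResult:
    """Exact posterior state probabilities via scaled forward-backward.

    The chain is reinitialized from pi0 at every session break; the returned
    log-likelihood is the sum of per-session log-marginals.  Emission rows
    that underflow to zero under every state are floored so the recursion
    never produces NaN.
    """
    params.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    T, K = X.shape[0], params.K
    if session_lengths is None:
        session_lengths = [T]
    if sum(session_lengths) != T:
        raise ValueError("session_lengths must sum to the number of trials")

    B = np.maximum(_emission_matrix(params, X, y), 1e-300)
    gamma = np.zeros((T, K))
    xi = np.zeros((max(T - 1, 0), K, K))
    loglik = 0.0
    pi0 = np.ascontiguousarray(params.pi0)
    A = np.ascontiguousarray(params.A)

    start = 0
    for L in session_lengths:
        loglik += _fb_session(pi0, A, B, gamma, xi, start, L)
        start += L

    return DecodeResult(gamma=gamma, xi=xi, loglik=loglik,
                        session_lengths=list(session_lengths))


def _weighted_logistic(
    X: np.ndarray, y: np.ndarray, weights: np.ndarray,
    w0: np.ndarray, ridge: float, max_iter: int = 50, tol: float = 1e-10,
) -> np.ndarray:
    """Newton-Raphson fit of weighted logistic regression with an L2 penalty
    on the non-bias coefficients (the last column is the constant).

    Steps are backtracked (halved) until the penalized objective does not
    increase, so the solver cannot diverge from a poor starting point."""

    def objective(w):
        z = X @ w
        # -sum_i weights_i * log p(y_i) in a stable form
        nll = float(np.dot(weights, np.logaddexp(0.0, z) - y * z))
        return nll + 0.5 * float(np.dot(pen, w * w))

    w = w0.copy()
    pen = np.full(X.shape[1], ridge)
    pen[-1] = 0.0
    f = objective(w)
    for _ in range(max_iter):
        p = expit(X @ w)
        grad = X.T @ (weights * (p - y)) + pen * w
        Wdiag = weights * p * (1 - p)
        H = (X * Wdiag[:, None]).T @ X + np.diag(pen + 1e-10)
        step = np.linalg.solve(H, grad)
        scale = 1.0
        for _ in range(40):
            w_new = w - scale * step
            f_new = objective(w_new)
            if f_new <= f + 1e-12:
                break
            scale /= 2
        else:
            break       # no improving step: converged or stalled
        moved = np.max(np.abs(scale * step))
        w, f = w_new, f_new
        if moved < tol:
            break
    return w


def _random_init(K: int, rng: np.random.Generator) -> GLMHMMParams:
    W = rng.normal(0.0, 1.0, size=(K, N_FEATURES))
    A = np.full((K, K), 0.05 / max(K - 1, 1)) + np.diag(np.full(K, 0.95 - 0.05))
    A = A + rng.dirichlet(np.ones(K) * 5, size=K) * 0.1
    A /= A.sum(axis=1, keepdims=True)
    pi0 = rng.dirichlet(np.ones(K) * 5)
    return GLMHMMParams(W, A, pi0)


@dataclass
class EMResult:
    params: GLMHMMParams
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int


def em_fit(
    X: np.ndarray,
    y: np.ndarray,
    session_lengths: list[int],
    K: int,
    n_restarts: int = 20,
    max_iter: int = 200,
    tol: float = 1e-6,
    ridge: float = 1e-4,
    rng: np.random.Generator | int | None = None,
    init: GLMHMMParams | None = None,
) -> EMResult:
    """Fit a K-state GLM-HMM by EM, returning the best of ``n_restarts``
    random initializations (or a single run from ``init`` if given).

    Convergence is declared when the relative log-likelihood improvement
    falls below ``tol``; a non-converged best run raises a warning but is
    still returned.  The per-iteration log-likelihood is non-decreasing up
    to numerical slack, a property the test suite checks on every fit.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(rng)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()

    starts = np.cumsum([0] + list(session_lengths))[:-1]
    best: EMResult | None = None
    inits = [init] if init is not None else [_random_init(K, rng) for _ in range(n_restarts)]

    for params in inits:
        params = GLMHMMParams(params.W.copy(), params.A.copy(), params.pi0.copy())
        trace = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            dec = forward_backward(params, X, y, session_lengths)
            trace.append(dec.loglik)
            if len(trace) >= 2:
                prev, cur = trace[-2], trace[-1]
                if abs(cur - prev) < tol * (abs(prev) + 1e-12):
                    converged = True
                    break
            # M-step
            pi0 = dec.gamma[starts].sum(axis=0)
            pi0 /= pi0.sum()
            # xi rows at session ends were left as zeros, safe to sum over all
            A = dec.xi.sum(axis=0) + 1e-12
            A /= A.sum(axis=1, keepdims=True)
            W = np.stack([
                _weighted_logistic(X, y, dec.gamma[:, k], params.W[k], ridge)
                for k in range(K)
            ])
            params = GLMHMMParams(W, A, pi0)
        final = forward_backward(params, X, y, session_lengths)
        if trace and final.loglik >= trace[-1] - 1e-8:
            trace.append(final.loglik)
        res = EMResult(params, np.array(trace), converged, it)
        if best is None or res.loglik_trace[-1] > best.loglik_trace[-1]:
            best = res

    assert best is not None
    if not best.converged:
        warnings.warn("EM did not converge within max_iter", RuntimeWarning)
    return best


def select_num_states(
    X: np.ndarray,
    y: np.ndarray,
    session_lengths: list[int],
    K_list: list[int],
    n_folds: int = 4,
    rng: np.random.Generator | int | None = None,
    **fit_kwargs,
):
    """Session-level cross-validated held-out log-likelihood per K.

    Folds split whole sessions (never trials); returns a table of the mean
    held-out log-likelihood per trial for each K for inspection — no plateau
    or elbow decision is automated.
    """
    import pandas as pd

    if not K_list:
        raise ValueError("K_list must be nonempty")
    rng = np.random.default_rng(rng)
    n_sessions = len(session_lengths)
    n_folds = min(n_folds, n_sessions)
    order = rng.permutation(n_sessions)
    folds = np.array_split(order, n_folds)
    bounds = np.cumsum([0] + list(session_lengths))
    sl = [slice(bounds[i], bounds[i + 1]) for i in range(n_sessions)]

    rows = []
    for K in K_list:
        per_fold = []
        for fold in folds:
            test_set = set(fold.tolist())
            tr = [i for i in range(n_sessions) if i not in test_set]
            te = sorted(test_set)
            y_te = np.concatenate([y[sl[i]] for i in te])
            if len(set(y_te.tolist())) < 2:
                warnings.warn("fold without both choice classes skipped", RuntimeWarning)
                continue
            X_tr = np.concatenate([X[sl[i]] for i in tr])
            y_tr = np.concatenate([y[sl[i]] for i in tr])
            len_tr = [session_lengths[i] for i in tr]
            fit = em_fit(X_tr, y_tr, len_tr, K, rng=rng, **fit_kwargs)
            X_te = np.concatenate([X[sl[i]] for i in te])
            len_te = [session_lengths[i] for i in te]
            dec = forward_backward(fit.params, X_te, y_te, len_te)
            per_fold.append(dec.loglik / len(y_te))
        rows.append({"K": K,
                     "heldout_loglik_per_trial": float(np.mean(per_fold)) if per_fold else np.nan,
                     "n_folds_used": len(per_fold)})
    return pd.DataFrame(rows)


def canonical_permutation(params: GLMHMMParams) -> np.ndarray:
    """Permutation putting a 3-state model in canonical order: state 1 has
    the largest |delta-cues| weight, state 2 the largest summed
    |previous-choice| weights among the rest, state 3 the remainder.
    Ties break toward the lower original index.  Non-3-state models map to
    the identity."""
    if params.K != 3:
        return np.arange(params.K)
    dc = np.abs(params.W[:, 0])
    s1 = int(np.argmax(dc))
    rest = [k for k in range(3) if k != s1]
    hist = np.abs(params.W[:, 1]) + np.abs(params.W[:, 2])
    s2 = rest[0] if hist[rest[0]] >= hist[rest[1]] else rest[1]
    s3 = rest[1] if s2 == rest[0] else rest[0]
    return np.array([s1, s2, s3])


def relabel_states(
    params: GLMHMMParams, decode: DecodeResult | None = None
) -> tuple[GLMHMMParams, DecodeResult | None, np.ndarray]:
    """Apply the canonical K=3 state ordering consistently to parameters and
    (optionally) a decode.  Returns (params, decode, permutation)."""
    perm = canonical_permutation(params)
    new_params = params.permuted(perm)
    new_decode = decode
    if decode is not None:
        new_decode = DecodeResult(
            gamma=decode.gamma[:, perm],
            xi=decode.xi[:, perm][:, :, perm],
            loglik=decode.loglik,
            session_lengths=decode.session_lengths,
        )
    return new_params, new_decode, perm


def state_occupancy(decode: DecodeResult) -> np.ndarray:
    """Fraction of trials whose posterior probability is greatest for each
    state (ties resolve to the lowest state index)."""
    T, K = decode.gamma.shape
    counts = np.bincount(decode.map_states, minlength=K)
    return counts / T


def per_state_trial_mask(
    decode: DecodeResult, state: int, threshold: float = 0.8
) -> np.ndarray:
    """Trials confidently assigned to ``state``: gamma[t, state] strictly
    greater than ``threshold`` (a posterior of exactly 0.8 is excluded)."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    return decode.gamma[:, state] > threshold
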