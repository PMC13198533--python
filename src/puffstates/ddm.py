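"""Discrete-pulse drift-diffusion model of within-trial evidence integration.

An accumulator a(t) starts at 0 and receives a signed unit deflection for
each airpuff (right = +1, left = -1), each corrupted by additive Gaussian
per-pulse noise with variance sigma2_s.  Between pulses the accumulator
drifts exponentially, da = lam * a * dt + diffusion noise of variance
sigma2_a per unit time; lam < 0 gives leaky integration with storage time
constant tau = -1/lam, lam > 0 instability.  The choice is right when the
final accumulator exceeds a bias threshold, except on a lapse fraction of
trials where the response is random.

Without decision bounds the final accumulator is Gaussian with closed-form
moments, giving an analytic choice likelihood:

    mu     = sum_i s_i exp(lam (T - t_i))
    sigma2 = sigma2_s sum_i exp(2 lam (T - t_i)) + sigma2_a (e^{2 lam T}-1)/(2 lam)
    P(right) = lapse/2 + (1 - lapse) Phi((mu - bias) / sigma)

with the lam -> 0 diffusion limit sigma2_a * T.  Fitting repeats a bounded
quasi-Newton optimization (log-transformed variances, logit-transformed
lapse) from random starts on random 80% subsamples of trials and summarizes
the repetitions by their median, SD and 2.5-97.5 percentile range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit, ndtr

_LAM_EPS = 1e-9       # |lam| below this uses the lam -> 0 limit branch
_P_FLOOR = 1e-12      # probability floor before taking logs

PARAM_NAMES = ("lam", "sigma2_a", "sigma2_s", "bias", "lapse")


@dataclass
class DDMParams:
    """Accumulator parameters.

    lam: memory drift, 1/s (negative = leaky, positive = unstable).
    sigma2_a: diffusion variance of the accumulator, units^2/s.
    sigma2_s: per-pulse Gaussian variance, units^2.
    bias: decision threshold on the final accumulator, units.
    lapse: probability of a random response, in [0, 1].
    """

    lam: float = 0.0
    sigma2_a: float = 0.0
    sigma2_s: float = 0.0
    bias: float = 0.0
    lapse: float = 0.0

    def __post_init__(self):
        if self.sigma2_a < 0 or self.sigma2_s < 0:
            raise ValueError("variances must be nonnegative")
        if not (0 <= self.lapse <= 1):
            raise ValueError("lapse must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.lam, self.sigma2_a, self.sigma2_s, self.bias, self.lapse])

    @classmethod
    def from_array(cls, a) -> "DDMParams":
        return cls(*(float(v) for v in a))


@dataclass
class PulseTrial:
    """Pulse times and signs (+1 right, -1 left) over a trial of duration T
    seconds (cue end); pulses at exactly T contribute with decay factor 1."""

    pulse_times: list[tuple[float, int]]
    T: float

    def __post_init__(self):
        for t, s in self.pulse_times:
            if not (0 <= t <= self.T):
                raise ValueError(f"pulse at {t}s outside [0, {self.T}]")
            if s not in (-1, 1):
                raise ValueError("pulse sign must be +1 or -1")


def trials_to_arrays(trials: list[PulseTrial]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pad ragged pulse lists into (times, signs, pulse_mask, T) arrays for
    vectorized likelihood evaluation."""
    n = len(trials)
    m = max((len(t.pulse_times) for t in trials), default=0)
    times = np.zeros((n, m))
    signs = np.zeros((n, m))
    mask = np.zeros((n, m), dtype=bool)
    T = np.array([t.T for t in trials], dtype=float)
    for i, tr in enumerate(trials):
        for j, (t, s) in enumerate(tr.pulse_times):
            times[i, j], signs[i, j], mask[i, j] = t, s, True
    return times, signs, mask, T


def _moments_arrays(params: DDMParams, times, signs, mask, T):
    """Vectorized final-accumulator mean and variance per trial."""
    lam = params.lam
    dt_rem = np.where(mask, T[:, None] - times, 0.0)   # remaining time per pulse
    decay = np.where(mask, np.exp(lam * dt_rem), 0.0)
    mu = (signs * decay).sum(axis=1)
    var_s = params.sigma2_s * np.where(mask, decay**2, 0.0).sum(axis=1)
    if abs(lam) < _LAM_EPS:
        var_a = params.sigma2_a * T
    else:
        var_a = params.sigma2_a * (np.exp(2 * lam * T) - 1.0) / (2 * lam)
    return mu, np.maximum(var_s + var_a, 0.0)


def accumulator_moments(params: DDMParams, trial: PulseTrial) -> tuple[float, float]:
    """Mean and variance of the final accumulator a(T) for one trial."""
    mu, var = _moments_arrays(params, *trials_to_arrays([trial]))
    return float(mu[0]), float(var[0])


def _choice_prob_arrays(params: DDMParams, times, signs, mask, T) -> np.ndarray:
    mu, var = _moments_arrays(params, times, signs, mask, T)
    sigma = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (mu - params.bias) / sigma
    phi = np.where(sigma > 0, ndtr(np.where(sigma > 0, z, 0.0)),
                   np.where(mu > params.bias, 1.0,
                            np.where(mu < params.bias, 0.0, 0.5)))
    return params.lapse / 2 + (1 - params.lapse) * phi


def choice_prob_right(params: DDMParams, trial: PulseTrial) -> float:
    """Probability of a rightward choice under the analytic Gaussian model."""
    return float(_choice_prob_arrays(params, *trials_to_arrays([trial]))[0])


def negative_log_likelihood(
    params: DDMParams,
    trials: list[PulseTrial] | tuple,
    choices: np.ndarray,
) -> float:
    """-sum log P(choice_t); choices coded 1 = right, 0 = left.  ``trials``
    may be a list of PulseTrial or a pre-padded array tuple from
    :func:`trials_to_arrays`."""
    arrays = trials if isinstance(trials, tuple) else trials_to_arrays(trials)
    p_right = _choice_prob_arrays(params, *arrays)
    y = np.asarray(choices).ravel()
    p = np.where(y == 1, p_right, 1.0 - p_right)
    return float(-np.log(np.maximum(p, _P_FLOOR)).sum())


def nll_gradient(params: DDMParams, trials, choices) -> np.ndarray:
    """Analytic gradient of the negative log-likelihood in the natural
    parameters (lam, sigma2_a, sigma2_s, bias, lapse)."""
    times, signs, mask, T = trials if isinstance(trials, tuple) else trials_to_arrays(trials)
    lam = params.lam
    y = np.asarray(choices).ravel()

    dt_rem = np.where(mask, T[:, None] - times, 0.0)
    decay = np.where(mask, np.exp(lam * dt_rem), 0.0)
    mu = (signs * decay).sum(axis=1)
    sum_d2 = np.where(mask, decay**2, 0.0).sum(axis=1)
    if abs(lam) < _LAM_EPS:
        var_a_unit = T.copy()            # (e^{2 lam T} - 1)/(2 lam) -> T
        dvar_a_unit = T**2               # d/dlam of the above -> T^2
    else:
        e2 = np.exp(2 * lam * T)
        var_a_unit = (e2 - 1.0) / (2 * lam)
        dvar_a_unit = T * e2 / lam - (e2 - 1.0) / (2 * lam**2)
    var = params.sigma2_s * sum_d2 + params.sigma2_a * var_a_unit
    sigma = np.sqrt(np.maximum(var, 1e-300))

    z = (mu - params.bias) / sigma
    phi_pdf = np.exp(-0.5 * z**2) / np.sqrt(2 * np.pi)
    Phi = ndtr(z)
    p_right = params.lapse / 2 + (1 - params.lapse) * Phi
    p = np.where(y == 1, p_right, 1.0 - p_right)
    p = np.maximum(p, _P_FLOOR)
    # dNLL/dp_right, sign-flipped for left choices
    dl_dpr = np.where(y == 1, -1.0 / p, 1.0 / p)

    dmu_dlam = (signs * decay * dt_rem).sum(axis=1)
    dvar_dlam = params.sigma2_s * 2 * np.where(mask, decay**2 * dt_rem, 0.0).sum(axis=1) \
        + params.sigma2_a * dvar_a_unit
    dz_dmu = 1.0 / sigma
    dz_dvar = -z / (2 * var)
    dpr_dz = (1 - params.lapse) * phi_pdf

    g_lam = dl_dpr * dpr_dz * (dz_dmu * dmu_dlam + dz_dvar * dvar_dlam)
    g_s2a = dl_dpr * dpr_dz * dz_dvar * var_a_unit
    g_s2s = dl_dpr * dpr_dz * dz_dvar * sum_d2
    g_bias = dl_dpr * dpr_dz * (-1.0 / sigma)
    g_lapse = dl_dpr * (0.5 - Phi)
    return np.array([g_lam.sum(), g_s2a.sum(), g_s2s.sum(), g_bias.sum(), g_lapse.sum()])


# ---------------------------------------------------------------- fitting

DEFAULT_BOUNDS = {
    "lam": (-10.0, 10.0),
    "log_sigma2": (np.log(1e-6), np.log(100.0)),
    "bias": (-10.0, 10.0),
    "logit_lapse": (-9.0, 9.0),
}


def _pack(p: DDMParams) -> np.ndarray:
    lo, hi = DEFAULT_BOUNDS["logit_lapse"]
    lapse = np.clip(p.lapse, expit(lo), expit(hi))
    return np.array([
        p.lam,
        np.log(max(p.sigma2_a, 1e-6)),
        np.log(max(p.sigma2_s, 1e-6)),
        p.bias,
        np.log(lapse / (1 - lapse)),
    ])


def _unpack(theta: np.ndarray) -> DDMParams:
    return DDMParams(
        lam=float(theta[0]),
        sigma2_a=float(np.exp(theta[1])),
        sigma2_s=float(np.exp(theta[2])),
        bias=float(theta[3]),
        lapse=float(expit(theta[4])),
    )


def _objective(theta, arrays, y):
    p = _unpack(theta)
    nll = negative_log_likelihood(p, arrays, y)
    g = nll_gradient(p, arrays, y)
    # chain rule through the transforms
    jac = np.array([1.0, p.sigma2_a, p.sigma2_s, 1.0, p.lapse * (1 - p.lapse)])
    return nll, g * jac


def _optimize_once(arrays, y, theta0):
    bounds = [
        DEFAULT_BOUNDS["lam"], DEFAULT_BOUNDS["log_sigma2"],
        DEFAULT_BOUNDS["log_sigma2"], DEFAULT_BOUNDS["bias"],
        DEFAULT_BOUNDS["logit_lapse"],
    ]
    res = optimize.minimize(_objective, theta0, args=(arrays, y), jac=True,
                            method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 300})
    return _unpack(res.x), float(res.fun), bool(res.success)


def _random_theta(rng: np.random.Generator) -> np.ndarray:
    return np.array([
        rng.uniform(-3, 3),
        rng.uniform(np.log(1e-3), np.log(5.0)),
        rng.uniform(np.log(1e-3), np.log(5.0)),
        rng.uniform(-1, 1),
        rng.uniform(-4, 2),
    ])


@dataclass
class DDMFitSummary:
    """Repetition summary of a multi-restart, trial-dropout fit: elementwise
    median, SD, and 2.5-97.5 percentile range over converged repetitions."""

    per_rep_params: list[DDMParams]
    median_params: DDMParams
    sd_params: np.ndarray
    range95_params: np.ndarray          # (2, 5): lower and upper percentiles
    dropout_fraction: float
    n_reps: int
    n_failed: int = 0

    def range95(self, name: str) -> tuple[float, float]:
        i = PARAM_NAMES.index(name)
        return float(self.range95_params[0, i]), float(self.range95_params[1, i])

    def to_dict(self, include_reps: bool = False) -> dict:
        d = {
            "median_params": dict(zip(PARAM_NAMES, self.median_params.as_array().tolist())),
            "sd_params": dict(zip(PARAM_NAMES, self.sd_params.tolist())),
            "range95_low": dict(zip(PARAM_NAMES, self.range95_params[0].tolist())),
            "range95_high": dict(zip(PARAM_NAMES, self.range95_params[1].tolist())),
            "dropout_fraction": self.dropout_fraction,
            "n_reps": self.n_reps,
            "n_failed": self.n_failed,
        }
        if include_reps:
            d["per_rep_params"] = [p.as_array().tolist() for p in self.per_rep_params]
        return d


def fit_ddm(
    trials: list[PulseTrial],
    choices: np.ndarray,
    n_reps: int = 1000,
    dropout: float = 0.2,
    rng: np.random.Generator | int | None = None,
    init: DDMParams | None = None,
) -> DDMFitSummary:
    """Fit by repeated randomized optimization with trial dropout.

    Each repetition omits a random ``dropout`` fraction of trials and runs a
    bounded quasi-Newton optimization from a random initialization (or from
    ``init`` when given).  The summary reports the elementwise median, SD
    and 2.5-97.5 percentile range over converged repetitions.
    """
    rng = np.random.default_rng(rng)
    y = np.asarray(choices).ravel()
    n = len(trials)
    if n < 2:
        raise ValueError("need at least 2 trials")
    arrays_full = trials_to_arrays(trials)

    keep_n = max(2, int(round(n * (1 - dropout))))
    fits, n_failed = [], 0
    for _ in range(n_reps):
        idx = rng.choice(n, size=keep_n, replace=False) if dropout > 0 else np.arange(n)
        y_sub = y[idx]
        if y_sub.min() == y_sub.max():
            n_failed += 1
            continue
        arrays = tuple(a[idx] for a in arrays_full[:3]) + (arrays_full[3][idx],)
        theta0 = _pack(init) if init is not None else _random_theta(rng)
        p, nll, ok = _optimize_once(arrays, y_sub, theta0)
        if ok and np.isfinite(nll):
            fits.append(p.as_array())
        else:
            n_failed += 1
    if not fits:
        raise RuntimeError(f"all {n_reps} repetitions failed (n={n} trials)")

    F = np.stack(fits)
    return DDMFitSummary(
        per_rep_params=[DDMParams.from_array(f) for f in F],
        median_params=DDMParams.from_array(np.median(F, axis=0)),
        sd_params=F.std(axis=0, ddof=1) if len(F) > 1 else np.zeros(5),
        range95_params=np.percentile(F, [2.5, 97.5], axis=0),
        dropout_fraction=dropout,
        n_reps=n_reps,
        n_failed=n_failed,
    )


@dataclass
class AccumulatorTrajectory:
    """Accumulator values on a uniform time grid from 0 to T."""

    times: np.ndarray
    a: np.ndarray


def simulate_trajectory(
    params: DDMParams,
    trial: PulseTrial,
    dt: float = 0.015,
    rng: np.random.Generator | int | None = None,
) -> AccumulatorTrajectory:
    """Euler-Maruyama simulation of one accumulator trajectory.

    Per step: a <- a + lam*a*dt + (pulses in the bin, each s_i + N(0,
    sigma2_s)) + sqrt(sigma2_a*dt)*N(0,1).  Deterministic when both
    variances are zero.  Pulses at exactly T land in the final bin.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(rng)
    n = int(np.ceil(trial.T / dt - 1e-12))
    times = np.concatenate([np.arange(n) * dt, [trial.T]])
    pulse_bins: dict[int, list[int]] = {}
    for t, s in trial.pulse_times:
        b = min(int(t / dt), n - 1)
        pulse_bins.setdefault(b, []).append(s)

    a = np.zeros(len(times))
    for i in range(n):
        step_dt = times[i + 1] - times[i]
        da = params.lam * a[i] * step_dt
        for s in pulse_bins.get(i, []):
            da += s + (rng.normal(0, np.sqrt(params.sigma2_s)) if params.sigma2_s > 0 else 0.0)
        if params.sigma2_a > 0:
            da += np.sqrt(params.sigma2_a * step_dt) * rng.normal()
        a[i + 1] = a[i] + da
    return AccumulatorTrajectory(times=times, a=a)


def simulate_final_values(
    params: DDMParams, trial: PulseTrial, n_draws: int,
    dt: float = 0.001, rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Vectorized Euler-Maruyama ensemble of final accumulator values,
    used as a Monte-Carlo cross-check of the analytic moments/likelihood."""
    rng = np.random.default_rng(rng)
    n = int(np.ceil(trial.T / dt - 1e-12))
    edges = np.concatenate([np.arange(n) * dt, [trial.T]])
    pulse_bins: dict[int, list[int]] = {}
    for t, s in trial.pulse_times:
        b = min(int(t / dt), n - 1)
        pulse_bins.setdefault(b, []).append(s)
    a = np.zeros(n_draws)
    for i in range(n):
        step_dt = edges[i + 1] - edges[i]
        a += params.lam * a * step_dt
        for s in pulse_bins.get(i, []):
            a += s
            if params.sigma2_s > 0:
                a += rng.normal(0, np.sqrt(params.sigma2_s), size=n_draws)
        if params.sigma2_a > 0:
            a += np.sqrt(params.sigma2_a * step_dt) * rng.normal(size=n_draws)
    return a


def leak_to_time_constant(lam: float) -> float:
    """Storage time constant tau = -1/lam for a leaky accumulator (lam < 0).

    Undefined for lam >= 0 (unstable accumulation or perfect memory).
    """
    if lam >= 0:
        raise ValueError("time constant undefined for lam >= 0")
    return -1.0 / lam


def cross_validated_bic(
    trials: list[PulseTrial],
    choices: np.ndarray,
    n_folds: int = 5,
    rng: np.random.Generator | int | None = None,
    n_reps: int = 10,
) -> tuple[float, float]:
    """(mean held-out log-likelihood per trial, BIC of the full-data fit).

    BIC = k ln(n) + 2*NLL with k = 5 free parameters; the held-out term is
    the mean per-trial log probability of test-fold choices under parameters
    fitted to the training folds.  Degenerate folds (one choice class) are
    skipped with a warning.
    """
    import warnings as _w

    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(rng)
    y = np.asarray(choices).ravel()
    n = len(trials)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)

    full = fit_ddm(trials, y, n_reps=n_reps, dropout=0.0, rng=rng)
    nll_full = negative_log_likelihood(full.median_params, trials, y)
    bic = 5 * np.log(n) + 2 * nll_full

    held = []
    for fold in folds:
        test = np.zeros(n, dtype=bool)
        test[fold] = True
        y_tr = y[~test]
        if y_tr.min() == y_tr.max() or y[test].size == 0:
            _w.warn("degenerate fold skipped", RuntimeWarning)
            continue
        fit = fit_ddm([t for t, m in zip(trials, ~test) if m], y_tr,
                      n_reps=n_reps, dropout=0.0, rng=rng)
        nll_te = negative_log_likelihood(
            fit.median_params, [t for t, m in zip(trials, test) if m], y[test])
        held.append(-nll_te / int(test.sum()))
    return (float(np.mean(held)) if held else float("nan")), float(bic)
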