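"""Behavioral statistics: psychometric curves, learning-rate survival
analysis, compositional occupancy statistics, effect aggregation, and PSTH
latency/area metrics.

Learning rate is summarized with the Kaplan-Meier product-limit estimator of
training-completion probability over trials, with mice that never finished
treated as right-censored, and groups compared with the log-rank test.
Per-mouse 3-state occupancy vectors live on the unit simplex and are
analyzed in Aitchison log-ratio geometry (zero imputation, compositional
means, radial confidence radii, ternary coordinates).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import erf

from .task_sim import LearningTimeRecord


# ------------------------------------------------------------ psychometric

@dataclass
class PsychometricParams:
    """Erf psychometric curve with independent low/high lapse rates:

    p(right | x) = g_low + (1 - g_low - g_high) * 0.5*(1 + erf((x - bias)/(sqrt(2)*slope)))

    bias and slope in delta-cues units; lapses in [0, 0.5].
    """

    bias: float
    slope: float
    gamma_low: float
    gamma_high: float

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not (0 <= self.gamma_low <= 0.5 and 0 <= self.gamma_high <= 0.5):
            raise ValueError("lapse rates must lie in [0, 0.5]")
        if self.gamma_low + self.gamma_high >= 1:
            raise ValueError("lapse rates must sum to < 1")

    def prob_right(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        core = 0.5 * (1 + erf((x - self.bias) / (math.sqrt(2) * self.slope)))
        return self.gamma_low + (1 - self.gamma_low - self.gamma_high) * core


def fit_psychometric(delta_cues, n_right, n_total=None) -> PsychometricParams:
    """Maximum-binomial-likelihood psychometric fit.

    Call either with per-trial data (``delta_cues``, 0/1 ``n_right`` choices,
    ``n_total=None``) or with per-bin counts (distinct ``delta_cues`` values,
    rightward counts, totals).  Requires at least 4 distinct stimulus values
    and both choice classes represented.
    """
    x = np.asarray(delta_cues, dtype=float)
    r = np.asarray(n_right, dtype=float)
    if n_total is None:
        # aggregate per-trial data into bins
        ux = np.unique(x)
        tot = np.array([(x == v).sum() for v in ux], dtype=float)
        r = np.array([r[x == v].sum() for v in ux], dtype=float)
        x = ux
    else:
        tot = np.asarray(n_total, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 distinct delta-cues values")
    if r.sum() == 0 or (tot - r).sum() == 0:
        raise ValueError("degenerate data: all choices on one side")

    def nll(theta):
        bias, log_slope, gl, gh = theta
        core = 0.5 * (1 + erf((x - bias) / (math.sqrt(2) * math.exp(log_slope))))
        p = np.clip(gl + (1 - gl - gh) * core, 1e-9, 1 - 1e-9)
        return float(-(r * np.log(p) + (tot - r) * np.log(1 - p)).sum())

    span = max(x.max() - x.min(), 1.0)
    best = None
    for s0 in (span / 8, span / 3):
        for g0 in (0.02, 0.15):
            res = optimize.minimize(
                nll, x0=[float(np.median(x)), math.log(s0), g0, g0],
                method="L-BFGS-B",
                bounds=[(x.min() - span, x.max() + span),
                        (math.log(1e-3 * span), math.log(10 * span)),
                        (0.0, 0.4999), (0.0, 0.4999)],
            )
            if best is None or res.fun < best.fun:
                best = res
    bias, log_slope, gl, gh = best.x
    return PsychometricParams(float(bias), float(math.exp(log_slope)),
                              float(gl), float(gh))


# ---------------------------------------------------------------- survival

@dataclass
class SurvivalCurve:
    """Product-limit estimate of the probability of *not yet* having
    completed training as a function of trials experienced."""

    times: np.ndarray           # sorted distinct event times
    survival: np.ndarray        # S(t) immediately after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray
    censor_times: np.ndarray
    median: float | None        # first event time with S(t) <= 0.5, or None

    def at(self, t: float) -> float:
        """S(t): survival just after time t (1.0 before the first event)."""
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])


def km_estimate(records: list[LearningTimeRecord]) -> SurvivalCurve:
    """Kaplan-Meier estimator of training completion with right-censoring.

    Completion is the event; mice that never completed are censored at the
    total trials they experienced.  Median is the first event time at which
    S drops to 0.5 or below, or None if S never reaches 0.5.
    """
    if not records:
        raise ValueError("need at least one record")
    times = np.array([r.trials_observed for r in records], dtype=float)
    events = np.array([r.completed for r in records], dtype=bool)

    ev_times = np.unique(times[events])
    surv, at_risk, n_ev = [], [], []
    s = 1.0
    for t in ev_times:
        n = int((times >= t).sum())      # censored at t are still at risk at t
        d = int(((times == t) & events).sum())
        s *= 1.0 - d / n
        surv.append(s)
        at_risk.append(n)
        n_ev.append(d)
    surv = np.array(surv)
    median = None
    below = np.nonzero(surv <= 0.5 + 1e-15)[0]
    if below.size:
        median = float(ev_times[below[0]])
    return SurvivalCurve(
        times=ev_times, survival=surv,
        n_at_risk=np.array(at_risk), n_events=np.array(n_ev),
        censor_times=np.sort(times[~events]), median=median,
    )


@dataclass
class LogRankResult:
    chi2: float
    df: int
    p: float


def logrank(records_by_group: dict[str, list[LearningTimeRecord]]) -> LogRankResult:
    """Log-rank test comparing completion-time distributions across groups.

    Standard observed-minus-expected statistic with the hypergeometric
    variance at each distinct event time; df = number of groups - 1.
    """
    groups = list(records_by_group)
    G = len(groups)
    if G < 2:
        raise ValueError("need at least 2 groups")
    times, events, gidx = [], [], []
    for g, recs in enumerate(records_by_group.values()):
        for r in recs:
            times.append(r.trials_observed)
            events.append(r.completed)
            gidx.append(g)
    times = np.array(times, dtype=float)
    events = np.array(events, dtype=bool)
    gidx = np.array(gidx)
    if not events.any():
        raise ValueError("log-rank undefined with zero events")

    ev_times = np.unique(times[events])
    OmE = np.zeros(G)
    V = np.zeros((G, G))
    for t in ev_times:
        at_risk = times >= t
        n = int(at_risk.sum())
        d = int(((times == t) & events).sum())
        if n <= 1:
            continue
        n_g = np.array([(at_risk & (gidx == g)).sum() for g in range(G)], dtype=float)
        d_g = np.array([(((times == t) & events) & (gidx == g)).sum() for g in range(G)],
                       dtype=float)
        e_g = d * n_g / n
        OmE += d_g - e_g
        hyp = d * (n - d) / (n - 1)
        V += hyp * (np.diag(n_g / n) - np.outer(n_g, n_g) / n**2)

    # quadratic form on the first G-1 components (the last is redundant)
    v = OmE[:-1]
    Vsub = V[:-1, :-1]
    chi2 = float(v @ np.linalg.pinv(Vsub) @ v) if v.size else 0.0
    df = G - 1
    return LogRankResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))


# ------------------------------------------------------------ compositional

_TINY = np.finfo(float).tiny     # smallest positive normalized float


def close_composition(raw) -> np.ndarray:
    """Closure of a 3-part occupancy vector with zero imputation.

    The vector is normalized to sum to one; zero components are replaced by
    the smallest positive normalized float and the total imputed mass is
    subtracted from the largest component, so log-ratios stay finite.
    """
    v = np.asarray(raw, dtype=float).copy()
    if v.shape != (3,):
        raise ValueError("composition must have 3 components")
    if np.any(v < 0):
        raise ValueError("occupancies must be nonnegative")
    total = v.sum()
    if total == 0:
        raise ValueError("all-zero composition")
    v /= total
    zero = v == 0
    if zero.any():
        v[zero] = _TINY
        v[int(np.argmax(v))] -= _TINY * zero.sum()
    s = v.sum()
    if abs(s - 1) > 1e-12:
        v /= s
    return v


def log_ratio(comp, num: int, den: int) -> float:
    """Natural log of the ratio of two components of a closed composition
    (0-based state indices)."""
    comp = np.asarray(comp, dtype=float)
    return float(np.log(comp[num]) - np.log(comp[den]))


def _clr(rows: np.ndarray) -> np.ndarray:
    logs = np.log(rows)
    return logs - logs.mean(axis=1, keepdims=True)


def compositional_mean_and_radius(
    rows, variant: str = "normal", level: float = 0.95
) -> tuple[np.ndarray, float | None]:
    """Compositional mean and a radial confidence radius on the log scale.

    Mean is the closure of per-component geometric means.  The radial
    standard deviation is the RMS Aitchison (clr-Euclidean) distance of rows
    from the mean with an N-1 divisor; the default radius is 1.96 x that SD.
    ``variant="fisher"`` instead scales the radial SD by
    sqrt(F_{level}(D-1, N-D+1)) — an alternative reading of confidence
    regions built from the F distribution.  Radius is None for N = 1.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    N, D = rows.shape
    gm = np.exp(np.log(rows).mean(axis=0))
    mean = gm / gm.sum()
    if N < 2:
        return mean, None
    d2 = ((_clr(rows) - _clr(mean[None, :]))**2).sum(axis=1)
    radial_sd = math.sqrt(d2.sum() / (N - 1))
    if variant == "normal":
        scale = 1.96
    elif variant == "fisher":
        scale = math.sqrt(stats.f.ppf(level, D - 1, N - D + 1))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return mean, scale * radial_sd


def ternary_coords(comp) -> tuple[float, float]:
    """Barycentric map of a 3-part composition onto the unit-side equilateral
    triangle with vertices (0,0), (1,0), (0.5, sqrt(3)/2) for states 1-3."""
    s1, s2, s3 = np.asarray(comp, dtype=float)
    return float(s2 + 0.5 * s3), float(math.sqrt(3) / 2 * s3)


# ---------------------------------------------------------- effect tables

@dataclass
class EffectTerm:
    """One labeled coefficient from an externally fitted mixed-effects model:
    a per-cluster baseline slope (state=None) or an interaction adjustment
    for a (state, cluster) condition."""

    label: str
    cluster: int
    estimate: float
    dispersion: float
    significant: bool
    state: int | None = None


def aggregate_marginal_effects(
    table: list[EffectTerm], state: int, cluster: int
) -> float:
    """Total per-puff effect for a (state, cluster) condition: the cluster's
    baseline slope plus all statistically significant interaction
    adjustments for that condition (insignificant terms contribute 0)."""
    baselines = [t for t in table if t.cluster == cluster and t.state is None]
    if not baselines:
        raise ValueError(f"no baseline slope for cluster {cluster}")
    total = baselines[0].estimate
    for t in table:
        if t.state == state and t.cluster == cluster and t.significant:
            total += t.estimate
    return total


# ------------------------------------------------------------------- PSTH

def psth_latency(
    times, rate, baseline_window, response_window, peak_sign: int = +1
) -> float:
    """Response latency: time at which the baseline-subtracted rate first
    reaches 30% of the first peak within the response window.

    The first peak is the extremum of the configured sign (use -1 for
    pause-type responses such as simple-spike suppression) inside the
    response window; the crossing is linearly interpolated between samples.
    A flat signal (zero peak) has no defined latency and raises.
    """
    times = np.asarray(times, dtype=float)
    rate = np.asarray(rate, dtype=float)
    b = (times >= baseline_window[0]) & (times <= baseline_window[1])
    w = (times >= response_window[0]) & (times <= response_window[1])
    if not w.any():
        raise ValueError("empty response window")
    delta = (rate - rate[b].mean()) * peak_sign
    dw = delta[w]
    tw = times[w]
    peak = dw.max()
    if peak <= 0:
        raise ValueError("flat or wrong-signed signal: latency undefined")
    thresh = 0.30 * peak
    above = np.nonzero(dw >= thresh)[0]
    i = above[0]
    if i == 0:
        return float(tw[0])     # already above at window start
    t0, t1 = tw[i - 1], tw[i]
    y0, y1 = dw[i - 1], dw[i]
    return float(t0 + (thresh - y0) / (y1 - y0) * (t1 - t0))


def psth_auc(times, rate, baseline_window, integration_window) -> float:
    """Signed area between the firing rate and its pre-stimulus baseline
    over the integration window (trapezoidal; units spikes = rate x time)."""
    times = np.asarray(times, dtype=float)
    rate = np.asarray(rate, dtype=float)
    b = (times >= baseline_window[0]) & (times <= baseline_window[1])
    w = (times >= integration_window[0]) & (times <= integration_window[1])
    delta = rate - rate[b].mean()
    return float(np.trapezoid(delta[w], times[w]))


def cohen_d_from_se(mean1: float, mean2: float, se: float, n: int) -> float:
    """Effect size from summary statistics: d = (mean1 - mean2) / (se * sqrt(n)),
    recovering the standard deviation as SE * sqrt(n)."""
    if se <= 0:
        raise ValueError("se must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    return (mean1 - mean2) / (se * math.sqrt(n))
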