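"""Synthetic generator for the pulsed-evidence accumulation task.

Head-fixed mice receive independent streams of randomly timed 40-ms airpuffs
on the left and right whiskers over a 1.0-3.8 s cue period, bracketed by a
bilateral marker puff at cue onset and offset, and report with a directional
lick which side carried more puffs.  This module simulates that stimulus
structure (homogeneous Poisson puff trains per side, thinned to a 200-ms
per-side refractory gap), the anti-biasing rule that assigns the correct
side, choice sequences generated from a latent-state Markov process with
state-specific Bernoulli GLMs, and group-level trials-to-criterion records
with right-censoring for learning-rate analysis.

Sides are coded left = -1, right = +1 throughout; times are seconds from cue
onset; trial indices are 0-based within a session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

LEFT = "left"
RIGHT = "right"
BILATERAL = "bilateral"

MIN_INTERPUFF_S = 0.200      # per-side refractory gap between puff onsets
PUFF_DURATION_S = 0.040      # metadata only; onsets carry the evidence
CUE_DURATION_RANGE = (1.0, 3.8)
DELAY_RANGE = (0.2, 0.8)

#: number of shaping levels; level 7 is the full task
N_LEVELS = 8


def side_sign(side: str) -> int:
    """Map a side label to its signed code (left=-1, right=+1)."""
    if side == LEFT:
        return -1
    if side == RIGHT:
        return +1
    raise ValueError(f"not a lateralized side: {side!r}")


def sign_side(sign: int) -> str:
    return RIGHT if sign > 0 else LEFT


@dataclass(frozen=True)
class PuffEvent:
    """A single airpuff onset.

    ``kind`` distinguishes the bilateral cue-period markers, the randomly
    timed evidence puffs, and the regular guide ("hint") puffs used in early
    shaping levels.
    """

    time: float
    side: str            # "left" | "right" | "bilateral"
    kind: str            # "marker" | "evidence" | "guide"

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("puff time must be >= 0")
        if self.side not in (LEFT, RIGHT, BILATERAL):
            raise ValueError(f"bad side {self.side!r}")
        if self.kind not in ("marker", "evidence", "guide"):
            raise ValueError(f"bad kind {self.kind!r}")
        if self.kind == "marker" and self.side != BILATERAL:
            raise ValueError("marker puffs are bilateral")


@dataclass
class TrialRecord:
    """One behavioral trial: stimulus, identifiers, choice and outcome.

    ``delta_cues`` is the number of right-side puffs minus left-side puffs,
    guide puffs included, bilateral markers excluded (they contribute equally
    to both sides, so either convention yields the same difference).
    ``latent_state`` is known only for synthetic data.
    """

    mouse_id: str
    session_id: str
    trial_index: int
    level: int
    cue_duration: float
    delay: float
    puffs: list[PuffEvent] = field(default_factory=list)
    n_left: int = 0
    n_right: int = 0
    delta_cues: int = 0
    correct_side: str = RIGHT
    choice: str = RIGHT
    rewarded: bool = False
    latent_state: int | None = None

    def validate(self) -> None:
        if not (CUE_DURATION_RANGE[0] <= self.cue_duration <= CUE_DURATION_RANGE[1]):
            raise ValueError(f"cue_duration {self.cue_duration} outside {CUE_DURATION_RANGE}")
        if self.delta_cues != self.n_right - self.n_left:
            raise ValueError("delta_cues != n_right - n_left")
        if self.rewarded != (self.choice == self.correct_side):
            raise ValueError("rewarded inconsistent with choice/correct_side")
        for side in (LEFT, RIGHT):
            onsets = sorted(
                p.time for p in self.puffs
                if p.kind in ("evidence", "guide") and p.side == side
            )
            gaps = np.diff(onsets)
            if len(gaps) and gaps.min() < MIN_INTERPUFF_S - 1e-12:
                raise ValueError(f"{side} interpuff gap below {MIN_INTERPUFF_S}s")


@dataclass
class LearningTimeRecord:
    """Trials-to-completion for one mouse; ``completed=False`` means the
    mouse was still training when observation ended (right-censored), and
    ``trials_observed`` is the total trials experienced up to that point."""

    mouse_id: str
    group: str
    trials_observed: int
    completed: bool

    def __post_init__(self):
        if self.trials_observed <= 0:
            raise ValueError("trials_observed must be positive")


def _poisson_onsets_with_refractory(
    rate: float, lo: float, hi: float, rng: np.random.Generator
) -> list[float]:
    """Homogeneous Poisson onsets in the open interval (lo, hi), greedily
    thinned so successive kept onsets are >= MIN_INTERPUFF_S apart."""
    if rate <= 0 or hi <= lo:
        return []
    n = rng.poisson(rate * (hi - lo))
    raw = np.sort(rng.uniform(lo, hi, size=n))
    kept: list[float] = []
    for t in raw:
        if t <= lo or t >= hi:
            continue
        if not kept or t - kept[-1] >= MIN_INTERPUFF_S:
            kept.append(float(t))
    return kept


def generate_trial_stimulus(
    rate_left: float,
    rate_right: float,
    cue_duration: float,
    guide_rate: float = 0.0,
    *,
    correct_side: str = RIGHT,
    guide_window: float = 2.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[PuffEvent], int, int, int]:
    """Generate the stimulus for one trial.

    Evidence onsets are drawn per side as a homogeneous Poisson process over
    the cue period, thinned to the 200-ms per-side refractory gap.  Bilateral
    marker puffs bracket the cue period at 0 and ``cue_duration``.  When
    ``guide_rate`` > 0 (shaping levels 1-2), guide puffs are placed at the
    regular interval 1/``guide_rate`` on ``correct_side`` only, starting one
    interval after cue offset and filling ``guide_window`` seconds.

    Returns ``(puffs, n_left, n_right, delta_cues)`` with counts over
    evidence + guide puffs (markers excluded; they cancel in the difference).
    """
    if rate_left < 0 or rate_right < 0 or guide_rate < 0:
        raise ValueError("puff rates must be nonnegative")
    if not (CUE_DURATION_RANGE[0] <= cue_duration <= CUE_DURATION_RANGE[1]):
        raise ValueError(f"cue_duration must lie in {CUE_DURATION_RANGE}")
    rng = np.random.default_rng(rng)

    puffs = [PuffEvent(0.0, BILATERAL, "marker")]
    counts = {LEFT: 0, RIGHT: 0}
    for side, rate in ((LEFT, rate_left), (RIGHT, rate_right)):
        for t in _poisson_onsets_with_refractory(rate, 0.0, cue_duration, rng):
            puffs.append(PuffEvent(t, side, "evidence"))
            counts[side] += 1
    puffs.append(PuffEvent(cue_duration, BILATERAL, "marker"))

    if guide_rate > 0:
        period = 1.0 / guide_rate
        n_guides = int(math.floor(guide_rate * guide_window + 1e-9))
        for k in range(1, n_guides + 1):
            puffs.append(PuffEvent(cue_duration + k * period, correct_side, "guide"))
            counts[correct_side] += 1

    puffs.sort(key=lambda p: p.time)
    n_left, n_right = counts[LEFT], counts[RIGHT]
    return puffs, n_left, n_right, n_right - n_left


# Internal logistic scale for the anti-bias correction: a fully perseverating
# agent at gain 1 sees P(correct=preferred side) = expit(-4) ~ 0.018.
_ANTIBIAS_SCALE = 4.0
_ANTIBIAS_DECAY = 0.8


def apply_antibias(
    choice_history: list[int],
    reward_history: list[bool],
    gain: float,
    rng: np.random.Generator | int | None = None,
) -> str:
    """Assign the correct side for the next trial, leaning against the
    subject's recent choice bias.

    The bias is an exponentially weighted mean of signed choices (decay 0.8
    per trial); the correct side is drawn with
    ``P(right) = expit(-gain * 4 * bias)``, so ``gain = 0`` gives 50/50 and a
    large gain pushes the correct side opposite a perseverating agent,
    driving its chance reward level below 50%.  ``reward_history`` is
    accepted for interface compatibility but the default corrector tracks
    choices only.
    """
    if gain < 0:
        raise ValueError("gain must be >= 0")
    rng = np.random.default_rng(rng)
    if gain == 0 or not choice_history:
        p_right = 0.5
    else:
        # weights beyond ~100 trials are negligible at decay 0.8
        recent = choice_history[-100:]
        weights = _ANTIBIAS_DECAY ** np.arange(len(recent))[::-1]
        bias = float(np.dot(weights, recent) / weights.sum())
        p_right = 1.0 / (1.0 + math.exp(gain * _ANTIBIAS_SCALE * bias))
    return RIGHT if rng.random() < p_right else LEFT


@dataclass
class SessionSpec:
    """Conditions for simulating sessions of the full (level-7) task."""

    n_sessions: int = 10
    trials_per_session: int = 250
    rate_correct: float = 2.0      # evidence puffs/s on the correct side
    rate_error: float = 0.5        # evidence puffs/s on the other side
    antibias_gain: float = 1.0
    guide_rate: float = 0.0
    guide_window: float = 2.0
    level: int = 7
    mouse_id: str = "sim"

    def __post_init__(self):
        if self.n_sessions < 1 or self.trials_per_session < 1:
            raise ValueError("need at least one session and one trial")
        if min(self.rate_correct, self.rate_error) < 0:
            raise ValueError("rates must be nonnegative")


def simulate_glmhmm_behavior(
    spec: SessionSpec,
    params,  # glmhmm.GLMHMMParams
    rng: np.random.Generator | int | None = None,
) -> list[TrialRecord]:
    """Simulate choice behavior from a latent-state Markov process.

    The latent state restarts from the initial distribution at each session
    start and follows the transition matrix between trials.  Each trial's
    choice is a Bernoulli draw from the active state's GLM evaluated on the
    realized features (delta-cues, previous two choices, previous reward
    side, bias), so refitting the model to the output is a well-posed
    parameter-recovery problem.
    """
    from . import glmhmm  # deferred: avoid import cycle

    params.validate()
    rng = np.random.default_rng(rng)
    trials: list[TrialRecord] = []

    for s in range(spec.n_sessions):
        session_id = f"sess{s:03d}"
        state = int(rng.choice(params.K, p=params.pi0))
        prev: list[TrialRecord] = []
        for t in range(spec.trials_per_session):
            if t > 0:
                state = int(rng.choice(params.K, p=params.A[state]))
            choice_hist = [side_sign(tr.choice) for tr in prev]
            reward_hist = [tr.rewarded for tr in prev]
            target = apply_antibias(choice_hist, reward_hist, spec.antibias_gain, rng)
            rate_l = spec.rate_correct if target == LEFT else spec.rate_error
            rate_r = spec.rate_correct if target == RIGHT else spec.rate_error
            cue = float(rng.uniform(*CUE_DURATION_RANGE))
            delay = float(rng.uniform(*DELAY_RANGE))
            puffs, n_l, n_r, dc = generate_trial_stimulus(
                rate_l, rate_r, cue,
                guide_rate=spec.guide_rate, correct_side=target,
                guide_window=spec.guide_window, rng=rng,
            )
            # reward goes to the side with the greater realized count;
            # the anti-bias target breaks ties
            correct = sign_side(dc) if dc != 0 else target

            x = glmhmm.features_for_trial(dc, prev)
            p_right = glmhmm.emission_prob(params.W[state], x, RIGHT)
            choice = RIGHT if rng.random() < p_right else LEFT

            rec = TrialRecord(
                mouse_id=spec.mouse_id, session_id=session_id, trial_index=t,
                level=spec.level, cue_duration=cue, delay=delay, puffs=puffs,
                n_left=n_l, n_right=n_r, delta_cues=dc, correct_side=correct,
                choice=choice, rewarded=(choice == correct), latent_state=state,
            )
            prev.append(rec)
        trials.extend(prev)
    return trials


_FAMILIES = ("lognormal", "gamma", "degenerate")


@dataclass
class GroupSpec:
    """Trials-to-criterion distribution for one training group.

    ``family`` is one of lognormal (params: median, sigma of log), gamma
    (params: shape, scale), or degenerate (params: value); draws are rounded
    to whole trials.  Completion times past ``censor_horizon`` are censored
    at the horizon.
    """

    family: str
    params: dict
    n_mice: int
    censor_horizon: int

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; use one of {_FAMILIES}")
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")
        if self.censor_horizon <= 0:
            raise ValueError("censor_horizon must be positive")
        if any(v <= 0 for v in self.params.values()):
            raise ValueError("distribution parameters must be positive")


def generate_learning_times(
    group_specs: dict[str, GroupSpec],
    rng: np.random.Generator | int | None = None,
) -> list[LearningTimeRecord]:
    """Draw per-mouse trials-to-criterion with right-censoring per group."""
    rng = np.random.default_rng(rng)
    records: list[LearningTimeRecord] = []
    for group, spec in group_specs.items():
        if spec.family == "lognormal":
            draws = rng.lognormal(
                mean=math.log(spec.params["median"]),
                sigma=spec.params["sigma"], size=spec.n_mice,
            )
        elif spec.family == "gamma":
            draws = rng.gamma(spec.params["shape"], spec.params["scale"], size=spec.n_mice)
        else:  # degenerate
            draws = np.full(spec.n_mice, float(spec.params["value"]))
        for i, d in enumerate(draws):
            t = max(1, int(round(d)))
            completed = t <= spec.censor_horizon
            records.append(LearningTimeRecord(
                mouse_id=f"{group}_m{i:02d}", group=group,
                trials_observed=t if completed else spec.censor_horizon,
                completed=completed,
            ))
    return records
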