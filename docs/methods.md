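# Methods

## Task model and synthetic generator

The generator emulates the statistical structure of a two-sided
pulsed-evidence accumulation task.  Per trial and side, evidence puff onsets
are drawn from a homogeneous Poisson process over the cue period and thinned
greedily to enforce the 200-ms per-side refractory gap (the task description
specifies only "randomly timed" puffs with a minimum interval; a censored
Poisson process is the least-structured law satisfying that).  Bilateral
marker puffs sit at cue onset and offset; they add equally to both sides and
are excluded from the per-side counts, so Δcues is unaffected by the
convention.  Cue durations are uniform on [1.0, 3.8] s and delays uniform on
[0.2, 0.8] s.  Guide puffs (shaping levels 1–2) are placed on the correct
side at the regular interval 1/rate (default 2.5 Hz), starting one interval
after cue offset — the published description places them after the cue
period, until the first lick; here a configurable guide window (default 2 s)
stands in for the lick time, and guides within it are included in the
Δcues bookkeeping.  Because the first guide falls ≥ 0.4 s after cue offset,
the per-side refractory invariant holds across the evidence/guide boundary
by construction.

The anti-biasing rule is not specified in the source description (it cites
prior work), so the package implements a transparent surrogate with the same
documented consequence: an exponentially weighted mean of signed choices
(decay 0.8/trial, truncated at 100 trials where the weights are < 2e-10)
gives a bias b ∈ [−1, 1], and the correct side is drawn with
P(right) = σ(−4·gain·b).  Gain 0 restores 50/50; at gain 1 a fully
perseverating agent faces P(correct side = its side) ≈ 0.018, driving its
reward rate far below 50%, as the task's anti-biasing is reported to do.
The reward-history argument is accepted for interface stability but unused.

Choices are simulated from a ground-truth GLM-HMM: the latent state is drawn
from π₀ at each session start and from the transition matrix between trials,
and the choice is a Bernoulli draw from the active state's GLM on the
realized features.  The default ground truth mirrors the qualitative
three-state structure seen in trained mice: state 1 dominated by the Δcues
weight (2.0 log-odds/puff), state 2 by previous-choice weights (1.5, 0.8,
with a negative previous-reward weight −0.5, i.e. lose-stay/win-switch
pressure), state 3 near-zero weights; transitions are sticky (0.95
diagonal).  These numbers are package configuration chosen to be
qualitatively realistic, not measured values.  Per-group trials-to-criterion
are drawn from lognormal (default), gamma, or degenerate families and
right-censored at a horizon; lognormal medians around 2,500–3,300 trials
with log-SD 0.35 produce curves resembling published training times.

What the generator does *not* emulate: reaction times and lick dynamics,
within-session fatigue or satiety drifts, inter-mouse heterogeneity of GLM
weights, level promotion/demotion dynamics, and any stimulus adaptation.
Passing recovery tests therefore demonstrates correctness of the estimators
under the model's own assumptions, not robustness to real-data violations
of them.

## GLM-HMM

Features per trial: (Δcues, prev_choice_1, prev_choice_2, prev_reward,
bias≡1), with sides coded left = −1 / right = +1, history terms 0 where
unavailable at session boundaries, and prev_reward equal to the signed
correct side of the previous trial if rewarded, else 0.  Δcues enters
unscaled, so weights read as log-odds per puff.

Inference uses scaled forward–backward recursions per session (the chain is
reinitialized from π₀ at session starts; emissions are floored at 1e-300 so
impossible observations can never produce NaN), with a numba-compiled inner
loop and a pure-numpy fallback of identical arithmetic.  EM alternates exact
E-steps with closed-form updates of A and π₀ and per-state weighted logistic
regressions solved by damped Newton iterations: each Newton step is halved
until the ridge-penalized objective does not increase, which makes the
M-step monotone and immune to the divergence plain Newton exhibits from
poor initializations.  The ridge penalty is 1e-4 on non-bias weights (bias
unpenalized), the EM tolerance 1e-6 relative log-likelihood change, the
default 20 random restarts (reduced in test configurations).  Non-converged
fits return with a warning, never silently.

State relabeling for K = 3 orders states by |Δcues weight| (state 1), then
summed |previous-choice| weights (state 2), remainder (state 3), ties to the
lower original index; the permutation is applied consistently to W, A, π₀,
γ and ξ.  Occupancy is the argmax-fraction of posteriors with ties to the
lowest state index; per-state masks use a strict γ > 0.8 threshold (a
posterior of exactly 0.8 is excluded).  Model selection reports per-K mean
held-out log-likelihood per trial over session-level folds and deliberately
automates no plateau decision.

A caveat established by the package's own recovery harness: in a
high-accuracy state, prev_reward coincides with prev_choice_1 on every
rewarded trial, so the two regressors correlate at ≈ 0.95 among on-task
trials and only their *sum* is precisely estimable at realistic trial
counts (the individual weights trade off along the collinear direction with
a standard error of ~0.1–0.2 at 20,000 trials, for any estimator).  The
Δcues and bias weights, the summed history weights, transition diagonals
(±0.03), and confident-trial state labels all recover well.

## Drift-diffusion model

The accumulator a(t) starts at 0, receives sᵢ + N(0, σ²ₛ) at each pulse
(additive per-pulse noise; for unit pulses the additive and multiplicative
conventions coincide in distribution), diffuses with variance σ²ₐ per
second, and drifts as da = λ a dt.  There are no decision bounds and no
sensory adaptation, so the final accumulator is Gaussian:

- μ = Σᵢ sᵢ e^{λ(T−tᵢ)}
- σ² = σ²ₛ Σᵢ e^{2λ(T−tᵢ)} + σ²ₐ (e^{2λT}−1)/(2λ), with the limit σ²ₐT
  taken when |λ| < 1e-9 (the two branches agree to < 1e-6 relative at
  λ = ±1e-8)

and P(right) = lapse/2 + (1−lapse) Φ((μ−bias)/σ); at σ = 0 the Φ term
degenerates to 1/0/½ by the sign of μ−bias.  T is the cue offset; a pulse
at exactly T contributes with decay factor 1.  Likelihood probabilities are
floored at 1e-12 before logs; the gradient is analytic in all five natural
parameters (verified against central differences at 1e-5 relative in the
suite).

Fitting optimizes the transformed parameters (λ raw in [−10, 10], log
variances in [log 1e-6, log 100], bias raw, logit lapse in [−9, 9]) with
L-BFGS-B, repeated with random initializations on random 80% subsamples
(dropout 0.2); summaries are the elementwise median, SD, and 2.5–97.5
percentile range over converged repetitions, with failures counted.  The
published procedure uses 1,000 repetitions; the package defaults to 1,000
with reduced counts (20–100) in test and pipeline configurations, which the
recovery harness shows is sufficient for stable medians.  Note that the
repetition range is a *stability* summary, not a confidence interval: 80%
subsamples of one dataset spread about half as much as independent datasets
would, so the "95% range" covers the generating value only ~70% of the time
by construction.  Cross-validated accuracy is reported as mean held-out
log-probability per trial alongside BIC = 5 ln n + 2·NLL.  Trajectory
simulation is Euler–Maruyama at dt = 15 ms by default (O(dt) bias,
acceptable for visualization; the moments oracle uses 1–2 ms).

## Behavioral statistics

Psychometric curves use the erf form with independent low/high lapse rates,
p(x) = γ_low + (1−γ_low−γ_high)·½(1+erf((x−bias)/(√2·slope))), fitted by
binomial maximum likelihood from four starting points with lapses bounded
in [0, 0.5).  Kaplan–Meier treats training completion as the event and
non-completion as right-censoring at the last observed trial; the median is
the first event time with S ≤ 0.5 and is reported as missing (not infinite)
when S never reaches 0.5.  The log-rank test uses the standard
hypergeometric-variance quadratic form with df = groups − 1 (the published
χ² subscripts are inconsistent with two-group tests and are not
reproduced); it matches lifelines to 1e-8 and is calibrated (type-I error
≈ 0.05) under null simulations.

Compositional occupancies are closed to the simplex; zeros are imputed with
the smallest positive normalized float, subtracted from the largest
component (numerically invisible at double precision, but it keeps
log-ratios finite and the construction total exactly 1).  The compositional
mean is the closure of per-component geometric means; the radial SD is the
RMS Aitchison (clr) distance from the mean with an N−1 divisor, and the
default confidence radius is 1.96 × radial SD.  The published description
mixes a normal quantile with F-distribution degrees of freedom; since the
exact formula is ambiguous, a `variant="fisher"` flag substitutes
√F₀.₉₅(D−1, N−D+1) for 1.96 and the default stays with the plain normal
quantile.  Ternary coordinates map states 1–3 to (0,0), (1,0),
(0.5, √3/2); the map is affine in the composition.

Effect aggregation sums a cluster's baseline spike-per-puff slope with all
statistically significant interaction adjustments for a (state, cluster)
condition; insignificant terms contribute zero.  Mixed-model fitting itself
is out of scope — the table is an input.  PSTH latency takes the baseline
mean over a pre-stimulus window, finds the first peak (signed extremum,
sign −1 for pause-type responses) in the response window, and linearly
interpolates the first 30%-of-peak crossing; a response already above
threshold at the window start dates the latency to the window start, and a
flat signal raises.  AUC is the trapezoidal integral of the
baseline-subtracted rate.  Effect size from summary statistics is
d = (m₁−m₂)/(SE·√n).

## Determinism and problem sizes

Every stochastic stage draws from numpy Generators seeded through a single
top-level SeedSequence, so a serialized pipeline config determines every
output byte (config SHA-256 recorded in the metrics bundle).  The test
suite runs its recovery harnesses at sizes the package treats as standard
desk-scale experiments: 20,000 trials × 20 seeds for 3-state GLM-HMM
recovery (2 EM restarts), 10,000 trials for drift-diffusion recovery
(20–60 repetitions), 1e5-draw Euler–Maruyama ensembles at dt = 1 ms for the
likelihood cross-check, and 1,000 null replicates for log-rank calibration.

## Known limitations

- The GLM-HMM assumes stationary transitions without inputs and a single
  shared parameter set; per-subject hierarchy is out of scope.
- prev_choice/prev_reward weights are individually weakly identified in
  high-accuracy states (see above); report their sum when it matters.
- The drift-diffusion likelihood is choice-only (no reaction times) and
  unbounded (no absorbing decision bounds), matching the five-parameter
  discrete-evidence model it implements.
- Repetition 95% ranges from subsampled fits understate dataset-level
  uncertainty; treat them as stability diagnostics.
- The level-promotion shaping logic is represented only as configurable
  per-level (cue, delay, guide, criterion) tuples; the exact published
  promotion thresholds are not modeled.
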