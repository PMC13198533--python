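# puffstates

Behavioral-modeling pipeline for a pulsed-evidence accumulation task in
head-fixed mice.  In the task, independent streams of randomly timed 40-ms
airpuffs arrive on the left and right whiskers over a 1.0–3.8-s cue period
(bracketed by bilateral marker puffs, with a ≥200-ms per-side interpuff
interval), and the animal reports with a directional lick which side carried
more puffs.  The package is aimed at researchers who want to characterize
*how* such choices are made — which latent strategy the animal is in on each
trial, how evidence is integrated and stored within a trial, and how fast
different groups of animals learn the task — using synthetic data with known
ground truth, so every stage is testable by parameter recovery.

## What it computes

**Latent-state GLM-HMM.**  Each trial the animal occupies one of K hidden
states; state *k* emits choices through its own Bernoulli GLM,

&nbsp;&nbsp;&nbsp;&nbsp;P(right | state k, x) = σ(wₖ·x),&nbsp;&nbsp;
x = (Δcues, prev choice 1, prev choice 2, prev reward, bias),

where Δcues = (right − left puff count, guide puffs included).  States
follow a stationary Markov chain (transition matrix A, initial distribution
π₀, restarted at each session).  Fitting is by EM with scaled
forward–backward recursions; decoding yields per-trial posteriors γₜₖ, state
occupancies (fraction of trials argmax-assigned to each state), and
per-state trial masks (γ > 0.8).  For K = 3 states are canonically ordered:
state 1 evidence-driven ("on-task"), state 2 history-driven, state 3
disengaged.

**Discrete-pulse drift-diffusion model.**  Within a trial an accumulator
receives a signed unit deflection per puff (right = +1) with per-pulse noise
σ²ₛ, diffuses with variance σ²ₐ per second, and drifts as da = λ·a·dt
(λ < 0: leaky memory with time constant τ = −1/λ).  Without bounds the
final accumulator is Gaussian with closed-form moments, so the choice
likelihood P(right) = lapse/2 + (1−lapse)·Φ((μ−bias)/σ) is analytic, with
an analytic gradient for fast fitting.  Fits repeat bounded quasi-Newton
optimizations from random starts on random 80% subsamples and report the
median / SD / 2.5–97.5 percentile range over repetitions.

**Learning-rate and occupancy statistics.**  Kaplan–Meier product-limit
curves of training completion over trials (mice that never finish are
right-censored), log-rank group comparisons, erf-family psychometric curves
with independent lapse rates, Aitchison compositional analysis of 3-state
occupancy vectors (zero imputation, log-ratios, compositional means, radial
confidence radii, ternary coordinates), aggregation of significant
mixed-model spike-per-puff effects, and PSTH latency (30%-of-first-peak) and
area-under-curve metrics.

**Synthetic task generator.**  Refractory-thinned Poisson puff trains,
2.5-Hz guide puffs on the correct side in early shaping levels, an
anti-biasing rule that pushes perseverating agents below 50% reward, choice
sequences drawn from a ground-truth GLM-HMM, and per-group
trials-to-criterion draws with censoring.

## Worked example

```python
import numpy as np
from puffstates import glmhmm, task_sim, ddm
from puffstates.pipeline import default_true_params

true = default_true_params()                      # 3-state ground truth
spec = task_sim.SessionSpec(n_sessions=20, trials_per_session=250)
trials = task_sim.simulate_glmhmm_behavior(spec, true, rng=0)

X, y, lengths = glmhmm.build_design(trials)
fit = glmhmm.em_fit(X, y, lengths, K=3, n_restarts=2, rng=0)
decode = glmhmm.forward_backward(fit.params, X, y, lengths)
params, decode, _ = glmhmm.relabel_states(fit.params, decode)

print(f"log-likelihood/trial: {decode.loglik / len(y):.4f}")
print("occupancy:", np.round(glmhmm.state_occupancy(decode), 3))
print("state-1 weights:", np.round(params.W[0], 2))
print("state-2 weights:", np.round(params.W[1], 2))
mask = glmhmm.per_state_trial_mask(decode, 0, 0.8)
print(f"state-1 trials (posterior > 0.8): {mask.sum()}")
print("tau(state 1 leak -0.17):", round(ddm.leak_to_time_constant(-0.17), 1), "s")
```

prints

```
log-likelihood/trial: -0.5243
occupancy: [0.349 0.342 0.31 ]
state-1 weights: [2.21 0.   0.07 0.16 0.16]
state-2 weights: [ 0.07  1.58  0.38 -0.75  0.05]
state-1 trials (posterior > 0.8): 1442
tau(state 1 leak -0.17): 5.9 s
```

The refit recovers the generating structure from 5,000 trials: state 1 is
dominated by the Δcues weight (truth 2.0; each unit of Δcues adds ~2.2 to
the log-odds of a rightward lick), state 2 by the previous-choice weights
(truth 1.5/0.8), and the three states are occupied roughly equally, matching
the sticky generating chain.  The mask selects the trials confidently
assigned to the on-task state, e.g. for a per-state drift-diffusion or
psychometric fit; a leak rate of −0.17 s⁻¹ corresponds to a 5.9-s storage
time constant.

There is also a CLI mirroring the pipeline stages:

```bash
puffstates simulate --seed 1 --out-dir run1
puffstates fit-glmhmm run1/trials.csv --k 3 --seed 1 --out run1/glmhmm.json
puffstates decode run1/trials.csv run1/glmhmm.json
puffstates run-all --seed 1 --out-dir run1
```

## Layout

- `src/puffstates/task_sim.py` — stimuli, anti-biasing, latent-state
  behavior simulation, learning-time records
- `src/puffstates/glmhmm.py` — features, forward–backward, EM, decoding,
  relabeling, occupancy, state masks, model selection
- `src/puffstates/ddm.py` — analytic likelihood and gradient, trajectory
  simulation, multi-restart fitting, cross-validated BIC
- `src/puffstates/behavior_stats.py` — psychometrics, Kaplan–Meier,
  log-rank, compositional statistics, effect aggregation, PSTH metrics
- `src/puffstates/{io,pipeline,cli}.py` — file formats, deterministic
  end-to-end orchestration, command line
- `docs/methods.md` — models, assumptions, parameter choices, limitations
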