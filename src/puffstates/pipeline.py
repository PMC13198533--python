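"""End-to-end pipeline: simulate -> fit/decode GLM-HMM -> per-state DDM ->
occupancy/compositional summary -> survival analysis.

Every stochastic stage derives its random stream from the single top-level
seed through numpy SeedSequence spawning, so a serialized config fully
determines every output byte; a SHA-256 hash of the canonical config JSON is
recorded in the metrics bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import behavior_stats, ddm, glmhmm, io, task_sim

log = logging.getLogger("puffstates")

# Default ground-truth GLM-HMM used by the simulator: state 1 evidence-
# driven, state 2 history-driven with a rightward tilt, state 3 disengaged
# (near-zero weights).  Feature order: delta_cues, prev_choice_1,
# prev_choice_2, prev_reward, bias.
DEFAULT_TRUE_W = np.array([
    [2.0, 0.1, 0.0, 0.1, 0.2],
    [0.1, 1.5, 0.8, -0.5, 0.0],
    [0.1, 0.0, 0.0, 0.0, 0.3],
])
DEFAULT_TRUE_A = np.array([
    [0.95, 0.025, 0.025],
    [0.025, 0.95, 0.025],
    [0.025, 0.025, 0.95],
])
DEFAULT_TRUE_PI0 = np.array([0.4, 0.3, 0.3])


def default_true_params() -> glmhmm.GLMHMMParams:
    return glmhmm.GLMHMMParams(DEFAULT_TRUE_W.copy(), DEFAULT_TRUE_A.copy(),
                               DEFAULT_TRUE_PI0.copy())

# Per-state DDM ground truth for simulation fixtures: state 1 stable and
# low-noise, states 2-3 leaky and noisy, state 2 with a high lapse rate.
DEFAULT_STATE_DDMS = {
    1: ddm.DDMParams(lam=-0.17, sigma2_a=0.05, sigma2_s=0.3, bias=0.0, lapse=0.05),
    2: ddm.DDMParams(lam=-1.20, sigma2_a=1.0, sigma2_s=1.0, bias=0.0, lapse=0.65),
    3: ddm.DDMParams(lam=-0.95, sigma2_a=1.0, sigma2_s=1.0, bias=0.0, lapse=0.35),
}


@dataclass
class PipelineConfig:
    """Everything a run needs; one top-level seed drives all stages."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    # task simulation
    n_sessions: int = 20
    trials_per_session: int = 250
    rate_correct: float = 2.0
    rate_error: float = 0.5
    antibias_gain: float = 1.0
    # GLM-HMM
    K: int = 3
    n_restarts: int = 2
    em_max_iter: int = 150
    em_tol: float = 1e-6
    state_threshold: float = 0.8
    # DDM
    ddm_n_reps: int = 50
    ddm_dropout: float = 0.2
    # survival
    n_mice_per_group: int = 12
    group_medians: tuple = (2500.0, 3300.0)
    group_sigma: float = 0.35
    censor_horizon: int = 6000

    def validate(self) -> None:
        if self.n_sessions < 1 or self.trials_per_session < 1:
            raise ValueError("need >= 1 session and >= 1 trial per session")
        if self.n_mice_per_group < 1:
            raise ValueError("n_mice_per_group must be >= 1")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not (0 < self.state_threshold < 1):
            raise ValueError("state_threshold must be in (0, 1)")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls(**data)


def _pulse_trials_from_records(trials: list[task_sim.TrialRecord]) -> list[ddm.PulseTrial]:
    out = []
    for t in trials:
        pulses = [(p.time, task_sim.side_sign(p.side))
                  for p in t.puffs if p.kind == "evidence" and p.time <= t.cue_duration]
        out.append(ddm.PulseTrial(pulse_times=pulses, T=t.cue_duration))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write trial tables, model JSONs and a metrics
    bundle under ``config.out_dir``; returns the metrics dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(5)
    metrics: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                     "stages": {}}

    def stage(name):
        log.info("stage %s starting", name)
        return time.perf_counter()

    # --- simulate -------------------------------------------------------
    t0 = stage("simulate")
    true_params = default_true_params()
    spec = task_sim.SessionSpec(
        n_sessions=config.n_sessions, trials_per_session=config.trials_per_session,
        rate_correct=config.rate_correct, rate_error=config.rate_error,
        antibias_gain=config.antibias_gain,
    )
    trials = task_sim.simulate_glmhmm_behavior(
        spec, true_params, rng=np.random.default_rng(seeds[0]))
    io.write_trial_table(trials, out / "trials.csv", out / "puffs.json")
    metrics["stages"]["simulate"] = {"n_trials": len(trials),
                                     "seconds": round(time.perf_counter() - t0, 3)}

    # --- fit + decode GLM-HMM ------------------------------------------
    t0 = stage("glmhmm")
    X, y, lengths = glmhmm.build_design(trials)
    fit = glmhmm.em_fit(X, y, lengths, K=config.K, n_restarts=config.n_restarts,
                        max_iter=config.em_max_iter, tol=config.em_tol,
                        rng=np.random.default_rng(seeds[1]))
    decode = glmhmm.forward_backward(fit.params, X, y, lengths)
    params_c, decode_c, perm = glmhmm.relabel_states(fit.params, decode)
    (out / "glmhmm.json").write_text(json.dumps(
        {**params_c.to_dict(), "relabeled": True,
         "loglik": decode_c.loglik, "converged": fit.converged}))
    io.append_decode_columns(out / "trials.csv", decode_c.gamma)
    occupancy = glmhmm.state_occupancy(decode_c)
    metrics["stages"]["glmhmm"] = {
        "loglik_per_trial": decode_c.loglik / len(y),
        "occupancy": occupancy.tolist(),
        "converged": fit.converged,
        "seconds": round(time.perf_counter() - t0, 3),
    }

    # --- per-state DDM fits --------------------------------------------
    t0 = stage("ddm")
    pulse_trials = _pulse_trials_from_records(trials)
    choices = np.array([1 if t.choice == task_sim.RIGHT else 0 for t in trials])
    ddm_rng = np.random.default_rng(seeds[2])
    ddm_summaries = {}
    for k in range(config.K):
        mask = glmhmm.per_state_trial_mask(decode_c, k, config.state_threshold)
        sub_t = [t for t, m in zip(pulse_trials, mask) if m]
        sub_y = choices[mask]
        if len(sub_t) < 50 or sub_y.min() == sub_y.max():
            ddm_summaries[f"state_{k + 1}"] = {"skipped": True, "n_trials": len(sub_t)}
            continue
        summ = ddm.fit_ddm(sub_t, sub_y, n_reps=config.ddm_n_reps,
                           dropout=config.ddm_dropout, rng=ddm_rng)
        d = summ.to_dict()
        d["n_trials"] = len(sub_t)
        lam = summ.median_params.lam
        d["time_constant_s"] = ddm.leak_to_time_constant(lam) if lam < 0 else None
        ddm_summaries[f"state_{k + 1}"] = d
    (out / "ddm.json").write_text(json.dumps(ddm_summaries))
    metrics["stages"]["ddm"] = {**{k: v.get("median_params", v)
                                   for k, v in ddm_summaries.items()},
                                "seconds": round(time.perf_counter() - t0, 3)}

    # --- compositional summary -----------------------------------------
    t0 = stage("compose")
    # per-session occupancies act as per-"mouse" compositions
    bounds = np.cumsum([0] + lengths)
    comps = []
    for i in range(len(lengths)):
        g = decode_c.gamma[bounds[i]:bounds[i + 1]]
        occ = np.bincount(np.argmax(g, axis=1), minlength=config.K) / g.shape[0]
        if config.K == 3:
            comps.append(behavior_stats.close_composition(occ))
    if comps:
        mean, radius = behavior_stats.compositional_mean_and_radius(np.stack(comps))
        metrics["stages"]["compose"] = {
            "mean": mean.tolist(), "radius": radius,
            "ternary_mean": list(behavior_stats.ternary_coords(mean)),
            "seconds": round(time.perf_counter() - t0, 3),
        }

    # --- survival -------------------------------------------------------
    t0 = stage("survival")
    m1, m2 = config.group_medians
    specs = {
        "boosted": task_sim.GroupSpec("lognormal", {"median": m1, "sigma": config.group_sigma},
                                      config.n_mice_per_group, config.censor_horizon),
        "control": task_sim.GroupSpec("lognormal", {"median": m2, "sigma": config.group_sigma},
                                      config.n_mice_per_group, config.censor_horizon),
    }
    records = task_sim.generate_learning_times(specs, rng=np.random.default_rng(seeds[3]))
    io.write_learning_times(records, out / "learning_times.csv")
    by_group = {g: [r for r in records if r.group == g] for g in specs}
    curves = {g: behavior_stats.km_estimate(rs) for g, rs in by_group.items()}
    lr = behavior_stats.logrank(by_group)
    metrics["stages"]["survival"] = {
        "medians": {g: c.median for g, c in curves.items()},
        "logrank_chi2": lr.chi2, "logrank_df": lr.df, "logrank_p": lr.p,
        "seconds": round(time.perf_counter() - t0, 3),
    }

    (out / "metrics.json").write_text(json.dumps(metrics, sort_keys=True, indent=2))
    log.info("pipeline complete: %s", out / "metrics.json")
    return metrics
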